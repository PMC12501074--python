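"""On-disk formats and per-site base-count primitives.

Every artifact the pipeline touches goes through this module: per-site
count tables (tab-separated, one row per site and sample, in the spirit of
three-letter-aligner conversion tables), SAM+FASTA pileup counting for
small fixtures, BED interval sets for region exclusion, calibration and
background tables, and the final call tables.

Coordinate conventions: count tables and call tables are 1-based inclusive
(pileup convention); BED output is 0-based half-open. Count tables are
transcript-sense: for reverse-strand alignments the pileup
reverse-complements base calls so that ``ref_base`` and the count columns
always read in the sense of the RNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

CONDITIONS = ("treated", "input1", "input2", "ivt")

#: Exact column order of the count-table TSV.
COUNT_COLUMNS = [
    "ref_id", "pos", "strand", "ref_base",
    "n_A", "n_C", "n_G", "n_T", "n_del",
    "sample_id", "condition", "replicate",
]

#: Exact column order of the calls TSV.
CALL_COLUMNS = [
    "ref_id", "pos", "strand", "motif",
    "depth_treated", "ratio_treated", "ratio_input1", "ratio_input2",
    "ratio_ivt", "fold_background", "fold_input2", "fold_ivt",
    "p_ttest", "p_binom", "d_fraction", "pass",
]

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class CountTableError(ValueError):
    """Schema or validation failure in a count table."""


@dataclass
class BaseCountRecord:
    """Base-call counts at one reference position for one sample.

    The unit of all calling. ``pos`` is 1-based on the reference;
    ``ref_base`` is the reference base in transcript sense. ``depth``
    is the number of base calls (deletions excluded).
    """

    ref_id: str
    pos: int
    strand: str
    ref_base: str
    n_A: int
    n_C: int
    n_G: int
    n_T: int
    n_del: int = 0
    sample_id: str = ""
    condition: str = "treated"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CountTableError(f"pos must be >= 1, got {self.pos}")
        if self.ref_base not in "ACGT":
            raise CountTableError(f"ref_base must be one of A/C/G/T, got {self.ref_base!r}")
        if self.strand not in "+-":
            raise CountTableError(f"strand must be '+' or '-', got {self.strand!r}")
        for name in ("n_A", "n_C", "n_G", "n_T", "n_del"):
            v = getattr(self, name)
            if v < 0:
                raise CountTableError(f"{name} must be non-negative, got {v}")
        if self.condition not in CONDITIONS:
            raise CountTableError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.replicate < 1:
            raise CountTableError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def depth(self) -> int:
        """Read coverage from base calls: n_A + n_C + n_G + n_T."""
        return self.n_A + self.n_C + self.n_G + self.n_T


def mutation_ratio(record: BaseCountRecord, mode: str = "tc") -> float | None:
    """Misincorporation ratio at a reference-T (uridine) site.

    ``tc`` mode (default) is the conversion-ratio semantics n_C/(n_C+n_T);
    ``any_mismatch`` is (depth - n_T)/depth. Returns ``None`` (undefined,
    not zero) when the denominator is empty. Deletions never enter either
    denominator: the D signal is misincorporation, not deletion.

    Raises ``ValueError`` at non-T sites — D is read out only at uridines.
    """
    if record.ref_base != "T":
        raise ValueError(
            f"mutation ratio is defined only at reference-T sites, "
            f"got ref_base={record.ref_base!r} at {record.ref_id}:{record.pos}"
        )
    if mode == "tc":
        denom = record.n_C + record.n_T
        return record.n_C / denom if denom else None
    if mode == "any_mismatch":
        denom = record.depth
        return (denom - record.n_T) / denom if denom else None
    raise ValueError(f"unknown mutation-ratio mode {mode!r}")


def motif_at(reference: str, pos: int) -> str:
    """5-mer sequence context centered on 1-based ``pos``, N-padded at ends."""
    if not 1 <= pos <= len(reference):
        raise ValueError(f"pos {pos} outside reference of length {len(reference)}")
    i = pos - 1
    padded = "NN" + reference.upper() + "NN"
    return padded[i : i + 5]


# ---------------------------------------------------------------------------
# Count-table TSV

def records_to_frame(records: Iterable[BaseCountRecord]) -> pd.DataFrame:
    """Materialize records as a DataFrame with the canonical column order."""
    rows = [
        (r.ref_id, r.pos, r.strand, r.ref_base, r.n_A, r.n_C, r.n_G, r.n_T,
         r.n_del, r.sample_id, r.condition, r.replicate)
        for r in records
    ]
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[BaseCountRecord]:
    return [
        BaseCountRecord(
            ref_id=str(row.ref_id), pos=int(row.pos), strand=str(row.strand),
            ref_base=str(row.ref_base), n_A=int(row.n_A), n_C=int(row.n_C),
            n_G=int(row.n_G), n_T=int(row.n_T), n_del=int(row.n_del),
            sample_id=str(row.sample_id), condition=str(row.condition),
            replicate=int(row.replicate),
        )
        for row in df.itertuples(index=False)
    ]


def as_count_frame(records) -> pd.DataFrame:
    """Accept either a DataFrame or an iterable of records."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in COUNT_COLUMNS if c not in records.columns]
        if missing:
            raise CountTableError(f"count frame missing columns: {missing}")
        return records
    return records_to_frame(records)


def read_count_table(path) -> list[BaseCountRecord]:
    """Read a per-site count table TSV into records.

    Lines starting with ``#`` are metadata and skipped. Malformed rows are
    reported with their 1-based line number.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    header_idx = None
    for i, line in enumerate(lines):
        if not line.startswith("#") and line.strip():
            header_idx = i
            break
    if header_idx is None:
        raise CountTableError(f"{path}: no header line found")
    header = lines[header_idx].rstrip("\n").split("\t")
    missing = [c for c in COUNT_COLUMNS if c not in header]
    if missing:
        raise CountTableError(f"{path}: missing required column(s): {', '.join(missing)}")
    col = {name: header.index(name) for name in COUNT_COLUMNS}
    records: list[BaseCountRecord] = []
    for lineno0, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < len(header):
            raise CountTableError(f"{path}:{lineno0}: expected {len(header)} fields, got {len(fields)}")
        try:
            records.append(BaseCountRecord(
                ref_id=fields[col["ref_id"]],
                pos=int(fields[col["pos"]]),
                strand=fields[col["strand"]],
                ref_base=fields[col["ref_base"]],
                n_A=int(fields[col["n_A"]]),
                n_C=int(fields[col["n_C"]]),
                n_G=int(fields[col["n_G"]]),
                n_T=int(fields[col["n_T"]]),
                n_del=int(fields[col["n_del"]]),
                sample_id=fields[col["sample_id"]],
                condition=fields[col["condition"]],
                replicate=int(fields[col["replicate"]]),
            ))
        except (ValueError, CountTableError) as exc:
            raise CountTableError(f"{path}:{lineno0}: {exc}") from exc
    return records


def write_count_table(records, path, header_lines: Sequence[str] = ()) -> None:
    df = as_count_frame(records)
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, columns=COUNT_COLUMNS)


# ---------------------------------------------------------------------------
# SAM pileup

def _load_reference(reference) -> dict[str, str]:
    if isinstance(reference, Mapping):
        return {k: str(v).upper() for k, v in reference.items()}
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(reference), "fasta")}


def pileup_from_sam(sam_path, reference, sample_id: str = "",
                    condition: str = "treated", replicate: int = 1,
                    min_mapq: int = 0) -> list[BaseCountRecord]:
    """Count aligned read bases per reference position from a SAM file.

    Only primary, mapped records are used. CIGAR-aware: M/=/X consume read
    and reference, I consumes read only, D increments the deletion tally,
    N skips reference, S/H are clipped. Reads with FLAG 0x10 (reverse
    strand) have their base calls reverse-complemented so output counts are
    transcript-sense; such positions are reported with strand '-' and
    ref_base complemented accordingly. MAPQ 0 reads are kept by default
    (multi-mapping is rampant in tRNA); raise ``min_mapq`` to drop them.

    ``reference`` is a FASTA path or a mapping of name -> sequence.
    """
    import pysam

    refs = _load_reference(reference)
    # counts[(ref_id, pos, strand)] = [n_A, n_C, n_G, n_T, n_del]
    counts: dict[tuple[str, int, str], list[int]] = {}
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            rname = read.reference_name
            if rname not in refs:
                raise KeyError(f"read {read.query_name!r} aligned to {rname!r}, absent from reference FASTA")
            strand = "-" if read.is_reverse else "+"
            seq = read.query_sequence or ""
            rpos = read.reference_start  # 0-based
            qpos = 0
            for op, length in read.cigartuples or []:
                if op in (0, 7, 8):  # M, =, X
                    for k in range(length):
                        base = seq[qpos + k].upper()
                        if strand == "-":
                            base = base.translate(COMPLEMENT)
                        key = (rname, rpos + k + 1, strand)
                        slot = counts.setdefault(key, [0, 0, 0, 0, 0])
                        if base in base_idx:
                            slot[base_idx[base]] += 1
                    rpos += length
                    qpos += length
                elif op == 1:  # I
                    qpos += length
                elif op == 2:  # D
                    for k in range(length):
                        key = (rname, rpos + k + 1, strand)
                        counts.setdefault(key, [0, 0, 0, 0, 0])[4] += 1
                    rpos += length
                elif op == 3:  # N
                    rpos += length
                elif op == 4:  # S
                    qpos += length
                # H (5), P (6): consume nothing

    records = []
    for (rname, pos, strand), (a, c, g, t, d) in sorted(counts.items()):
        ref_base = refs[rname][pos - 1]
        if strand == "-":
            ref_base = ref_base.translate(COMPLEMENT)
        records.append(BaseCountRecord(
            ref_id=rname, pos=pos, strand=strand, ref_base=ref_base,
            n_A=a, n_C=c, n_G=g, n_T=t, n_del=d,
            sample_id=sample_id, condition=condition, replicate=replicate,
        ))
    return records


# ---------------------------------------------------------------------------
# Region sets (BED)

class RegionSet:
    """Interval collection for point-overlap queries (0-based half-open)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self.intervals: list[tuple[str, int, int, str]] = []
        for ref_id, start, end, name in intervals:
            self.add(ref_id, start, end, name)

    def add(self, ref_id: str, start: int, end: int, name: str = "") -> None:
        if start >= end:
            raise ValueError(f"interval start must be < end, got [{start},{end})")
        self._trees.setdefault(ref_id, IntervalTree()).addi(start, end, name)
        self.intervals.append((ref_id, start, end, name))

    def contains(self, ref_id: str, pos_1based: int) -> bool:
        """Does any interval cover the given 1-based position?"""
        tree = self._trees.get(ref_id)
        return bool(tree is not None and tree[pos_1based - 1])

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        rs = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.rstrip("\n").split("\t")
                name = f[3] if len(f) > 3 else ""
                rs.add(f[0], int(f[1]), int(f[2]), name)
        return rs


# ---------------------------------------------------------------------------
# Calls

def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_calls(calls, path, format: str = "tsv",
                header_lines: Sequence[str] = ()) -> None:
    """Write finalized site calls as a detail TSV or as BED6.

    The TSV carries the full per-criterion record; ``pass`` is the
    semicolon-joined list of ``label=0|1`` criterion flags. BED intervals
    are 0-based half-open with score = round(1000 * D fraction).
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("\t".join(CALL_COLUMNS) + "\n")
            for c in calls:
                flags = ";".join(f"{k}={int(bool(v))}" for k, v in c.criteria.items())
                row = [
                    c.ref_id, c.pos, c.strand, c.motif,
                    c.depth_treated, c.ratio_treated, c.ratio_input1,
                    c.ratio_input2, c.ratio_ivt, c.fold_background,
                    c.fold_input2, c.fold_ivt, c.p_ttest, c.p_binom,
                    c.d_fraction,
                ]
                fh.write("\t".join(_fmt(v) for v in row) + f"\t{flags}\n")
    elif format == "bed":
        with open(path, "w") as fh:
            fh.write('track name="craci_calls"\n')
            for c in calls:
                frac = c.d_fraction if c.d_fraction is not None else 0.0
                score = round(1000 * frac)
                name = f"{c.ref_id}:{c.pos}:{c.motif}"
                fh.write(f"{c.ref_id}\t{c.pos - 1}\t{c.pos}\t{name}\t{score}\t{c.strand}\n")
    else:
        raise ValueError(f"unknown calls format {format!r}")


def read_calls(path) -> pd.DataFrame:
    """Read a calls TSV back as a DataFrame (with a boolean ``called`` column)."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise CountTableError(f"{path}: calls table missing column(s): {missing}")

    def _all_pass(flags: str) -> bool:
        return all(part.endswith("=1") for part in str(flags).split(";") if part)

    df["called"] = df["pass"].map(_all_pass)
    return df


# ---------------------------------------------------------------------------
# Calibration / background tables

def write_calibration_table(curves, path, header_lines: Sequence[str] = ()) -> None:
    """Persist per-motif curves: motif, slope_A, intercept_b, r2, n_points."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("motif\tslope_A\tintercept_b\tr2\tn_points\n")
        for curve in curves:
            fh.write(f"{curve.motif}\t{curve.slope_A:.10g}\t{curve.intercept_b:.10g}\t"
                     f"{_fmt(curve.r2)}\t{curve.n_points}\n")


def read_calibration_table(path):
    from craci.calibration import CalibrationCurve, CalibrationSet

    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    curves = [
        CalibrationCurve(motif=str(r.motif), slope_A=float(r.slope_A),
                         intercept_b=float(r.intercept_b),
                         r2=None if pd.isna(r.r2) else float(r.r2),
                         n_points=int(r.n_points))
        for r in df.itertuples(index=False)
    ]
    return CalibrationSet(curves)


def write_background_table(table, path, header_lines: Sequence[str] = ()) -> None:
    """Persist per-motif 0%-D misincorporation rates: motif, bg_ratio, depth."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("motif\tbg_ratio\tdepth\n")
        for motif in sorted(table.rates):
            fh.write(f"{motif}\t{table.rates[motif]:.10g}\t{table.depths.get(motif, 0)}\n")


def read_background_table(path):
    from craci.calibration import BackgroundTable

    df = pd.read_csv(path, sep="\t", comment="#")
    rates = {str(r.motif): float(r.bg_ratio) for r in df.itertuples(index=False)}
    depths = {str(r.motif): int(r.depth) for r in df.itertuples(index=False)}
    return BackgroundTable(rates=rates, depths=depths)
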