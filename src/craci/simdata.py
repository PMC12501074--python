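"""Seeded synthetic count tables with the statistical structure of
reduction-based D sequencing.

The generator emulates what the calling pipeline assumes about real
libraries: at every reference uridine the T->C misincorporation ratio
responds linearly to the true modified fraction f through motif-specific
parameters, y = clip(A*f + b, 0, 1); read counts are binomial at a
configurable depth; input and IVT libraries carry f = 0 so only the
background intercept remains; replicates are independent binomial draws.
A single integer seed drives everything through per-condition/replicate
substreams, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from craci.calibration import CalibrationPoint, enumerate_motifs
from craci.io_formats import COUNT_COLUMNS, motif_at, write_count_table
from craci.sitecall_ncrna import is_multi_u

#: Condition codes used to derive deterministic per-condition substreams.
_COND_CODE = {"treated": 1, "input1": 2, "input2": 3, "ivt": 4}

#: Fixed, uridine-free 15-nt flanks of the synthetic probe references, so
#: the probe's only candidate sites are inside the centered 5-mer.
_PROBE_FLANK_L = "GACCGAGCGACCGAC"
_PROBE_FLANK_R = "CAGCCGACGACCGAG"


@dataclass
class SimConfig:
    """Full parameterization of one synthetic dataset.

    ``truth`` is the planted-site list [(ref_id, pos, d_fraction_true)];
    leave it None to auto-plant ``n_true_sites`` sites with fractions drawn
    uniformly from ``true_fraction_range`` (a ``multi_u_fraction`` share of
    them in multi-U contexts, as negative controls for the exclusion
    criterion). ``depth`` is reads per site, fixed, or the Poisson mean
    when ``depth_poisson`` is set. ``input_background_scale`` multiplies
    the background intercept in input libraries.
    """

    seed: int = 0
    n_refs: int = 4
    ref_length: int = 400
    depth: int = 100
    depth_poisson: bool = False
    motif_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_A: float = 0.9
    default_b: float = 0.05
    truth: list[tuple[str, int, float]] | None = None
    n_true_sites: int = 10
    true_fraction_range: tuple[float, float] = (0.1, 0.9)
    multi_u_fraction: float = 0.0
    replicates: dict[str, int] = field(
        default_factory=lambda: {"treated": 2, "input1": 1, "input2": 1, "ivt": 2}
    )
    input_background_scale: float = 1.0
    error_rate: float = 0.0   # optional uniform miscall rate into A/G

    def __post_init__(self) -> None:
        if not 0.0 < self.default_A <= 1.0:
            raise ValueError(f"default_A must be in (0,1], got {self.default_A}")
        if not 0.0 <= self.default_b <= 0.2:
            raise ValueError(f"default_b must be in [0,0.2], got {self.default_b}")
        for motif, (A, b) in self.motif_params.items():
            if not 0.0 < A <= 1.0 or not 0.0 <= b <= 0.2:
                raise ValueError(f"motif_params[{motif}]: need A in (0,1], b in [0,0.2]")
        if self.truth is not None:
            for _, _, f in self.truth:
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"planted fraction out of [0,1]: {f}")


@dataclass
class SimResult:
    reference: dict[str, str]
    tables: dict[tuple[str, int], pd.DataFrame]   # (condition, replicate) -> counts
    truth: pd.DataFrame
    config: SimConfig


def _random_reference(rng: np.random.Generator, n_refs: int, length: int) -> dict[str, str]:
    bases = np.array(list("ACGT"))
    return {
        f"ref{i + 1:03d}": "".join(bases[rng.integers(0, 4, size=length)])
        for i in range(n_refs)
    }


def _eligible_t_positions(seq: str, want_multi_u: bool) -> list[int]:
    """1-based T positions with a full 5-mer inside the sequence."""
    out = []
    for pos in range(3, len(seq) - 1):
        if seq[pos - 1] != "T":
            continue
        if is_multi_u(motif_at(seq, pos), "adjacent") == want_multi_u:
            out.append(pos)
    return out


def choose_sites(reference: Mapping[str, str], n_sites: int,
                 fraction_range: tuple[float, float],
                 seed: int, multi_u_fraction: float = 0.0) -> list[tuple[str, int, float]]:
    """Deterministically pick planted sites among eligible reference T's.

    A ``multi_u_fraction`` share of the sites goes to multi-U contexts
    (these should never be called when the exclusion criterion is on).
    """
    rng = np.random.default_rng([seed, 99])
    n_multi = int(round(n_sites * multi_u_fraction))
    picks: list[tuple[str, int, float]] = []
    for want_multi, n_want in ((False, n_sites - n_multi), (True, n_multi)):
        pool = [
            (ref_id, pos)
            for ref_id, seq in sorted(reference.items())
            for pos in _eligible_t_positions(seq, want_multi)
        ]
        if n_want > len(pool):
            raise ValueError(
                f"cannot plant {n_want} sites: only {len(pool)} eligible "
                f"{'multi-U' if want_multi else 'single-U'} positions"
            )
        idx = rng.choice(len(pool), size=n_want, replace=False)
        lo, hi = fraction_range
        fracs = rng.uniform(lo, hi, size=n_want)
        picks.extend((pool[i][0], pool[i][1], float(f)) for i, f in zip(idx, fracs))
    return sorted(picks)


def simulate_counts(config: SimConfig) -> SimResult:
    """Generate reference, per-condition/replicate count tables, and truth.

    Per T site and replicate the expected treated ratio is
    y = clip(A*f + b, 0, 1) with (A, b) from ``motif_params`` (defaults for
    unlisted motifs); n_C ~ Binomial(N, y), n_T = N - n_C. Input and IVT
    libraries use f = 0 (inputs with the background intercept scaled by
    ``input_background_scale``). Only reference-T rows are emitted.
    """
    rng_ref = np.random.default_rng([config.seed, 0])
    reference = _random_reference(rng_ref, config.n_refs, config.ref_length)

    truth_list = config.truth
    if truth_list is None:
        truth_list = choose_sites(
            reference, config.n_true_sites, config.true_fraction_range,
            config.seed, config.multi_u_fraction,
        )
    truth_map: dict[tuple[str, int], float] = {}
    for ref_id, pos, f in truth_list:
        if reference[ref_id][pos - 1] != "T":
            raise ValueError(f"planted site {ref_id}:{pos} is not a reference T")
        truth_map[(ref_id, pos)] = f

    # site grid: every reference T, transcript sense
    site_ref, site_pos, site_motif = [], [], []
    for ref_id, seq in sorted(reference.items()):
        for i, base in enumerate(seq):
            if base == "T":
                site_ref.append(ref_id)
                site_pos.append(i + 1)
                site_motif.append(motif_at(seq, i + 1))
    n_sites = len(site_pos)
    A = np.array([config.motif_params.get(m, (config.default_A, config.default_b))[0]
                  for m in site_motif])
    b = np.array([config.motif_params.get(m, (config.default_A, config.default_b))[1]
                  for m in site_motif])
    f = np.array([truth_map.get((r, p), 0.0) for r, p in zip(site_ref, site_pos)])

    tables: dict[tuple[str, int], pd.DataFrame] = {}
    for condition, n_rep in sorted(config.replicates.items()):
        for rep in range(1, n_rep + 1):
            rng = np.random.default_rng([config.seed, _COND_CODE[condition], rep])
            if condition == "treated":
                y = np.clip(A * f + b, 0.0, 1.0)
            elif condition == "ivt":
                y = np.clip(b, 0.0, 1.0)
            else:
                y = np.clip(b * config.input_background_scale, 0.0, 1.0)
            if config.depth_poisson:
                N = rng.poisson(config.depth, size=n_sites)
            else:
                N = np.full(n_sites, config.depth)
            n_C = rng.binomial(N, y)
            n_T = N - n_C
            n_A = np.zeros(n_sites, dtype=int)
            n_G = np.zeros(n_sites, dtype=int)
            if config.error_rate > 0:
                n_A = rng.binomial(n_T, config.error_rate / 2)
                n_T = n_T - n_A
                n_G = rng.binomial(n_T, config.error_rate / 2)
                n_T = n_T - n_G
            sample = f"{condition}_rep{rep}"
            df = pd.DataFrame({
                "ref_id": site_ref, "pos": site_pos, "strand": "+", "ref_base": "T",
                "n_A": n_A, "n_C": n_C, "n_G": n_G, "n_T": n_T, "n_del": 0,
                "sample_id": sample, "condition": condition, "replicate": rep,
            })[COUNT_COLUMNS]
            tables[(condition, rep)] = df

    truth_df = pd.DataFrame(
        [(r, p, frac, motif_at(reference[r], p),
          is_multi_u(motif_at(reference[r], p), "adjacent"))
         for (r, p), frac in sorted(truth_map.items())],
        columns=["ref_id", "pos", "d_fraction_true", "motif", "multi_u"],
    )
    return SimResult(reference=reference, tables=tables, truth=truth_df, config=config)


def simulate_calibration_series(motifs: Sequence[str] | None = None,
                                levels: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
                                depth: int | None = 5000,
                                seed: int = 0,
                                motif_params: Mapping[str, tuple[float, float]] | None = None,
                                default_A: float = 0.9,
                                default_b: float = 0.05) -> list[CalibrationPoint]:
    """One binomial-sampled calibration point per (motif, mixture level).

    The defaults mirror the defined-mixture probe design: six levels from
    0% to 100% D in 20% steps. ``depth=None`` switches to the analytic
    expectation (infinite-depth) mode where points lie exactly on y = Ax+b.
    """
    if not levels:
        raise ValueError("empty mixture-level set")
    if any(not 0.0 <= x <= 1.0 for x in levels):
        raise ValueError("mixture levels must lie in [0,1]")
    if motifs is None:
        motifs = enumerate_motifs()
    motif_params = motif_params or {}
    points: list[CalibrationPoint] = []
    for m_idx, motif in enumerate(motifs):
        A, b = motif_params.get(motif, (default_A, default_b))
        rng = np.random.default_rng([seed, 5, m_idx])
        for x in levels:
            y_true = min(max(A * x + b, 0.0), 1.0)
            if depth is None:
                points.append(CalibrationPoint(motif, float(x), y_true, 0))
            else:
                k = int(rng.binomial(depth, y_true))
                points.append(CalibrationPoint(motif, float(x), k / depth, depth))
    return points


def make_probe_reference(motif: str) -> str:
    """Deterministic 35-nt probe with the 5-mer at positions 16-20 (1-based).

    Flanks carry no T, so the probe's only uridine candidates are those of
    the motif itself, and the central T sits at position 18.
    """
    if len(motif) != 5 or any(c not in "ACGTN" for c in motif):
        raise ValueError(f"invalid motif {motif!r}")
    return _PROBE_FLANK_L + motif + _PROBE_FLANK_R


def write_simulation(result: SimResult, outdir) -> dict[str, Path]:
    """Write FASTA, per-condition/replicate count TSVs, truth TSV, config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = outdir / "reference.fa"
    with open(fasta, "w") as fh:
        for ref_id, seq in sorted(result.reference.items()):
            fh.write(f">{ref_id}\n{seq}\n")
    paths["reference"] = fasta

    for (condition, rep), df in sorted(result.tables.items()):
        p = outdir / f"counts_{condition}_rep{rep}.tsv"
        write_count_table(df, p)
        paths[f"{condition}_rep{rep}"] = p

    truth_path = outdir / "truth.tsv"
    result.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path

    import yaml

    cfg_path = outdir / "sim_config.yaml"
    cfg = asdict(result.config)
    cfg["motif_params"] = {k: list(v) for k, v in cfg["motif_params"].items()}
    if cfg["truth"] is not None:
        cfg["truth"] = [list(t) for t in cfg["truth"]]
    cfg["true_fraction_range"] = list(cfg["true_fraction_range"])
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    paths["config"] = cfg_path
    return paths
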