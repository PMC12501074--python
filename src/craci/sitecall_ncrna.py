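"""Seven-criterion D site caller for tRNA and other ncRNA.

A candidate D site in a treated/input1/input2 library trio is called when,
at a reference-T position, (1) the treated misincorporation ratio exceeds
20% with more than five misincorporated reads, (2) both input ratios stay
below 15%, (3) coverage exceeds 50 in treated and both inputs, (4) the
treated ratio is more than 3-fold over the motif's 0%-D background,
(5) more than 3-fold over the Input2 ratio, (6) the site is not in a
multi-U context (adjacent uridines accumulate mutations during analysis),
and (7) the site is a uridine on the reference — enforced structurally by
evaluating only reference-T positions. "Above"/"below" are strict bounds.
Stoichiometry is attached by inverting the motif's calibration curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean, median
from typing import Iterable, Mapping

import pandas as pd

from craci.calibration import (
    BackgroundTable,
    CalibrationSet,
    FOLD_EPSILON,
    estimate_fraction,
)
from craci.io_formats import as_count_frame, motif_at, _load_reference

NCRNA_CRITERIA = (
    "treated_ratio", "input_ratio", "depth",
    "fold_background", "fold_input2", "not_multi_u", "u_site",
)


@dataclass
class NcrnaCallConfig:
    """Thresholds of the ncRNA caller; the defaults are the published cutoffs."""

    min_ratio_treated: float = 0.20   # strict: ratio must exceed this
    min_mis_count: int = 5            # strict: misincorporated reads must exceed this
    max_ratio_input: float = 0.15     # strict: each input ratio must stay below
    min_depth: int = 50               # strict: depth must exceed this, all libraries
    fold_over_background: float = 3.0
    fold_over_input2: float = 3.0
    exclude_multi_u: bool = True
    multi_u_mode: str = "adjacent"    # 'adjacent' (UU neighbor) or 'any' (extra U in 5-mer)
    ratio_mode: str = "tc"            # tc: C/(C+T); any_mismatch: (depth-T)/depth

    def __post_init__(self) -> None:
        if self.fold_over_background < 1 or self.fold_over_input2 < 1:
            raise ValueError("fold thresholds must be >= 1")
        if min(self.min_ratio_treated, self.min_mis_count,
               self.max_ratio_input, self.min_depth) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.multi_u_mode not in ("adjacent", "any"):
            raise ValueError(f"multi_u_mode must be 'adjacent' or 'any', got {self.multi_u_mode!r}")


@dataclass
class SiteCall:
    """One evaluated candidate site with per-criterion verdicts.

    ``criteria`` maps criterion label -> pass flag in evaluation order;
    ``called`` is the conjunction. ``flags`` carries soft annotations
    (missing data, calibration fallback, clamping, degenerate statistics).
    """

    ref_id: str
    pos: int
    strand: str
    motif: str
    depth_treated: int = 0
    depth_inputs: tuple[int, int] | None = None
    ratio_treated: float | None = None
    ratio_input1: float | None = None
    ratio_input2: float | None = None
    ratio_ivt: float | None = None
    mis_count_treated: int = 0
    fold_background: float | None = None
    fold_input2: float | None = None
    fold_ivt: float | None = None
    p_ttest: float | None = None
    p_binom: float | None = None
    d_fraction: float | None = None
    clamped: bool = False
    criteria: dict[str, bool] = field(default_factory=dict)
    called: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def site(self) -> tuple[str, int]:
        return (self.ref_id, self.pos)


def is_multi_u(motif: str, mode: str = "adjacent") -> bool:
    """Is the central uridine in a multi-U context?

    ``adjacent``: an immediate neighbor of the central base is also T.
    ``any``: any other position of the 5-mer is T (stricter).
    """
    if len(motif) != 5 or motif[2] != "T":
        raise ValueError(f"expected 5-mer with central T, got {motif!r}")
    if mode == "adjacent":
        return motif[1] == "T" or motif[3] == "T"
    if mode == "any":
        return "T" in (motif[:2] + motif[3:])
    raise ValueError(f"unknown multi-U mode {mode!r}")


def merge_replicates(records) -> pd.DataFrame:
    """Pool replicates of one condition by summing counts per site."""
    df = as_count_frame(records)
    merged = (
        df.groupby(["ref_id", "pos", "strand", "ref_base"], as_index=False)
        [["n_A", "n_C", "n_G", "n_T", "n_del"]].sum()
    )
    return merged


def _ratio_cols(df: pd.DataFrame, mode: str) -> pd.DataFrame:
    df = df.copy()
    df["depth"] = df[["n_A", "n_C", "n_G", "n_T"]].sum(axis=1)
    if mode == "tc":
        denom = df["n_C"] + df["n_T"]
        df["ratio"] = (df["n_C"] / denom).where(denom > 0)
        df["mis_count"] = df["n_C"]
    else:
        df["ratio"] = ((df["depth"] - df["n_T"]) / df["depth"]).where(df["depth"] > 0)
        df["mis_count"] = df["depth"] - df["n_T"]
    return df


def call_sites_ncrna(treated, input1, input2,
                     curves: CalibrationSet | None,
                     background: BackgroundTable,
                     reference: Mapping[str, str] | str,
                     config: NcrnaCallConfig | None = None) -> list[SiteCall]:
    """Evaluate every covered reference-T site against the seven criteria.

    Replicates within each condition are pooled by count summation before
    ratios are computed. Sites covered in treated but absent from an input
    are evaluated with missing-data flags and are never called. Returns one
    ``SiteCall`` per treated reference-T site, called or not.
    """
    cfg = config or NcrnaCallConfig()
    refs = _load_reference(reference)
    eps = FOLD_EPSILON

    t = _ratio_cols(merge_replicates(treated), cfg.ratio_mode)
    i1 = _ratio_cols(merge_replicates(input1), cfg.ratio_mode)
    i2 = _ratio_cols(merge_replicates(input2), cfg.ratio_mode)

    t = t[t["ref_base"] == "T"]
    key = ["ref_id", "pos", "strand"]
    keep = ["ratio", "depth"]
    m = t.merge(i1[key + keep], on=key, how="left", suffixes=("", "_i1"))
    m = m.merge(i2[key + keep], on=key, how="left", suffixes=("", "_i2"))
    m = m.rename(columns={"ratio_i1": "ratio_input1", "depth_i1": "depth_input1",
                          "ratio_i2": "ratio_input2", "depth_i2": "depth_input2"})

    calls: list[SiteCall] = []
    for row in m.itertuples(index=False):
        motif = motif_at(refs[row.ref_id], row.pos)
        flags: list[str] = []
        rt = row.ratio if pd.notna(row.ratio) else None
        r1 = row.ratio_input1 if pd.notna(row.ratio_input1) else None
        r2 = row.ratio_input2 if pd.notna(row.ratio_input2) else None
        d1 = int(row.depth_input1) if pd.notna(row.depth_input1) else 0
        d2 = int(row.depth_input2) if pd.notna(row.depth_input2) else 0
        if pd.isna(row.ratio_input1):
            flags.append("missing_input1")
        if pd.isna(row.ratio_input2):
            flags.append("missing_input2")
        if rt is None:
            flags.append("undefined_treated_ratio")

        bg, bg_fallback = background.get(motif)
        if bg_fallback:
            flags.append("background_fallback")

        crit: dict[str, bool] = {}
        crit["treated_ratio"] = (
            rt is not None
            and rt > cfg.min_ratio_treated
            and row.mis_count > cfg.min_mis_count
        )
        crit["input_ratio"] = (
            r1 is not None and r2 is not None
            and r1 < cfg.max_ratio_input and r2 < cfg.max_ratio_input
        )
        crit["depth"] = (
            row.depth > cfg.min_depth
            and d1 > cfg.min_depth and d2 > cfg.min_depth
        )
        crit["fold_background"] = (
            rt is not None and rt > cfg.fold_over_background * max(bg, eps)
        )
        crit["fold_input2"] = (
            rt is not None and r2 is not None
            and rt > cfg.fold_over_input2 * max(r2, eps)
        )
        crit["not_multi_u"] = (
            not is_multi_u(motif, cfg.multi_u_mode) if cfg.exclude_multi_u else True
        )
        crit["u_site"] = True  # only reference-T rows reach this loop

        d_fraction = None
        clamped = False
        if rt is not None and curves is not None and len(curves):
            curve, cal_fallback = curves.get(motif)
            if cal_fallback:
                flags.append("calibration_fallback")
            if curve is not None and curve.slope_A > 0:
                est = estimate_fraction(rt, curve)
                d_fraction, clamped = est.value, est.clamped
                if clamped:
                    flags.append("clamped")

        calls.append(SiteCall(
            ref_id=row.ref_id, pos=int(row.pos), strand=row.strand, motif=motif,
            depth_treated=int(row.depth), depth_inputs=(d1, d2),
            ratio_treated=rt, ratio_input1=r1, ratio_input2=r2,
            mis_count_treated=int(row.mis_count),
            fold_background=None if rt is None else rt / max(bg, eps),
            fold_input2=None if (rt is None or r2 is None) else rt / max(r2, eps),
            d_fraction=d_fraction, clamped=clamped,
            criteria=crit, called=all(crit.values()), flags=flags,
        ))
    return calls


@dataclass
class PositionSummary:
    label: str
    n: int
    mean: float
    median: float
    values: list[float]


def summarize_by_position(calls: Iterable[SiteCall],
                          annotation: Mapping[tuple[str, int], str]) -> dict[str, PositionSummary]:
    """Group call stoichiometries by canonical tRNA position label.

    ``annotation`` maps (ref_id, pos) to a label such as "16", "20a" or
    "47"; numbering itself is supplied by the user. Calls without an
    annotation entry fall into the "unannotated" bucket; calls without an
    estimated stoichiometry are skipped.
    """
    buckets: dict[str, list[float]] = {}
    for c in calls:
        if c.d_fraction is None:
            continue
        label = annotation.get((c.ref_id, c.pos), "unannotated")
        buckets.setdefault(label, []).append(c.d_fraction)
    return {
        label: PositionSummary(label=label, n=len(vals),
                               mean=mean(vals), median=median(vals), values=vals)
        for label, vals in sorted(buckets.items())
    }
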