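"""Eight-criterion D site caller for mRNA with an IVT background.

mRNA D sites are rare and low-stoichiometry, so the caller tests cellular
treated libraries against an in-vitro-transcribed (IVT), modification-free
copy of the transcriptome. The site universe is every reference-T position
covered in both cellular and IVT samples; a site is called when (1) the
pooled cellular ratio exceeds 20%, (2) the IVT ratio stays below 20%,
(3) a two-sided t-test between per-replicate cellular and IVT ratios gives
p < 0.05 and the cellular ratio exceeds 3-fold over IVT, (4) the site does
not overlap annotated tRNA regions, (5) the cellular ratio exceeds 2-fold
over both the motif background and the Input2 ratio, (6) cellular depth
exceeds 30, (7) the motif is not multi-U, and (8) a one-sided binomial
test of the misincorporation count against the motif background rate gives
p < 0.05 (optionally Benjamini-Hochberg adjusted across tested sites).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from craci.calibration import BackgroundTable, CalibrationSet, FOLD_EPSILON, estimate_fraction
from craci.io_formats import RegionSet, as_count_frame, motif_at, _load_reference
from craci.sitecall_ncrna import SiteCall, _ratio_cols, is_multi_u, merge_replicates

MRNA_CRITERIA = (
    "cell_ratio", "ivt_ratio", "ivt_ttest_fold", "not_trna",
    "fold_background_input2", "depth", "not_multi_u", "binom",
)


class InsufficientReplicatesError(ValueError):
    """A t-test group has fewer than two replicate values."""


@dataclass
class MrnaCallConfig:
    """Thresholds of the IVT-background mRNA caller (published defaults)."""

    min_ratio_cell: float = 0.20
    max_ratio_ivt: float = 0.20
    max_p_ttest: float = 0.05
    fold_over_ivt: float = 3.0
    fold_over_background: float = 2.0
    fold_over_input2: float = 2.0
    min_depth_cell: int = 30          # strict bound, as in the ncRNA caller
    exclude_multi_u: bool = True
    multi_u_mode: str = "adjacent"
    max_p_binom: float = 0.05
    multiple_testing: str = "none"    # 'none' or 'bh'
    binom_null: str = "background"    # 'background' (motif rate) or 'ivt'
    ttest: str = "welch"              # 'welch' or 'student'
    ratio_mode: str = "tc"

    def __post_init__(self) -> None:
        for p in (self.max_p_ttest, self.max_p_binom, self.min_ratio_cell, self.max_ratio_ivt):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability/ratio threshold out of [0,1]: {p}")
        for f in (self.fold_over_ivt, self.fold_over_background, self.fold_over_input2):
            if f < 1:
                raise ValueError(f"fold thresholds must be >= 1, got {f}")
        if self.multiple_testing not in ("none", "bh"):
            raise ValueError(f"multiple_testing must be 'none' or 'bh', got {self.multiple_testing!r}")
        if self.binom_null not in ("background", "ivt"):
            raise ValueError(f"binom_null must be 'background' or 'ivt', got {self.binom_null!r}")
        if self.ttest not in ("welch", "student"):
            raise ValueError(f"ttest must be 'welch' or 'student', got {self.ttest!r}")


def _ttest_p(a: np.ndarray, b: np.ndarray, equal_var: bool = False) -> np.ndarray:
    """Row-wise two-sided two-sample t-test p-values.

    ``a`` and ``b`` are (n_sites, n_replicates) matrices. Degenerate rows
    where both group variances are zero get p = 1 when the means agree and
    p = 0 when they differ. Rows with any NaN give NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se2 = sp2 * (1.0 / na + 1.0 / nb)
            df = np.full_like(se2, na + nb - 2)
        else:
            se2 = va / na + vb / nb
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = (ma - mb) / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p = np.where(degenerate & (ma == mb), 1.0, p)
    p = np.where(degenerate & (ma != mb), 0.0, p)
    nan_rows = np.isnan(a).any(axis=1) | np.isnan(b).any(axis=1)
    p[nan_rows] = np.nan
    return p


def welch_ttest_two_sided(a: Sequence[float], b: Sequence[float]) -> float:
    """Welch (unequal-variance) two-sided t-test between two ratio lists.

    Both groups need at least two values. When both variances are zero the
    p-value is 1 for equal means and 0 otherwise (degenerate convention).
    """
    if len(a) < 2 or len(b) < 2:
        raise InsufficientReplicatesError(
            f"each group needs >= 2 replicate values, got {len(a)} and {len(b)}"
        )
    p = _ttest_p(np.array([a]), np.array([b]), equal_var=False)
    return float(p[0])


def binom_test_greater(k: int, n: int, p0: float) -> float:
    """Exact one-sided upper-tail binomial p-value P[X >= k], X ~ Bin(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0,1], got {p0}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def _replicate_ratio_matrix(rep_frames: list[pd.DataFrame], universe: pd.DataFrame,
                            key: list[str]) -> np.ndarray:
    cols = []
    for rf in rep_frames:
        merged = universe[key].merge(rf[key + ["ratio"]], on=key, how="left")
        cols.append(merged["ratio"].to_numpy(dtype=float))
    return np.column_stack(cols)


def _as_rep_list(reps) -> list:
    """Accept a list of per-replicate collections or one frame with a replicate column."""
    if isinstance(reps, pd.DataFrame):
        return [g for _, g in reps.groupby("replicate")]
    reps = list(reps)
    if reps and not isinstance(reps[0], (pd.DataFrame, list)):
        # single flat record list: split on the replicate attribute
        byrep: dict[int, list] = {}
        for r in reps:
            byrep.setdefault(r.replicate, []).append(r)
        return [byrep[k] for k in sorted(byrep)]
    return reps


def call_sites_mrna(cell_treated_reps, ivt_treated_reps, input2,
                    curves: CalibrationSet | None,
                    background: BackgroundTable,
                    trna_regions: RegionSet | None,
                    reference: Mapping[str, str] | str,
                    config: MrnaCallConfig | None = None) -> list[SiteCall]:
    """Evaluate reference-T sites covered in both cellular and IVT samples.

    ``cell_treated_reps`` and ``ivt_treated_reps`` are per-replicate record
    collections (or a single table with a ``replicate`` column). Ratios for
    criteria other than the t-test are computed on count-pooled replicates;
    the t-test uses per-replicate ratios. With a single replicate in either
    condition the t-test criterion cannot be evaluated: such sites are
    flagged provisional and are never called.
    """
    cfg = config or MrnaCallConfig()
    refs = _load_reference(reference)
    eps = FOLD_EPSILON
    key = ["ref_id", "pos", "strand"]

    cell_list = _as_rep_list(cell_treated_reps)
    ivt_list = _as_rep_list(ivt_treated_reps)
    cell_rep_frames = [_ratio_cols(merge_replicates(r), cfg.ratio_mode) for r in cell_list]
    ivt_rep_frames = [_ratio_cols(merge_replicates(r), cfg.ratio_mode) for r in ivt_list]

    cell = _ratio_cols(merge_replicates(pd.concat([as_count_frame(r) for r in cell_list])),
                       cfg.ratio_mode)
    ivt = _ratio_cols(merge_replicates(pd.concat([as_count_frame(r) for r in ivt_list])),
                      cfg.ratio_mode)
    i2 = _ratio_cols(merge_replicates(input2), cfg.ratio_mode)

    cell = cell[(cell["ref_base"] == "T") & (cell["depth"] > 0)]
    ivt = ivt[ivt["depth"] > 0]
    uni = cell.merge(ivt[key + ["ratio", "depth"]], on=key, how="inner",
                     suffixes=("", "_ivt"))
    uni = uni.merge(i2[key + ["ratio"]].rename(columns={"ratio": "ratio_input2"}),
                    on=key, how="left")
    if uni.empty:
        return []

    n_sites = len(uni)
    replicated = len(cell_rep_frames) >= 2 and len(ivt_rep_frames) >= 2
    if replicated:
        a = _replicate_ratio_matrix(cell_rep_frames, uni, key)
        b = _replicate_ratio_matrix(ivt_rep_frames, uni, key)
        p_ttest = _ttest_p(a, b, equal_var=(cfg.ttest == "student"))
    else:
        p_ttest = np.full(n_sites, np.nan)

    motifs = [motif_at(refs[r], p) for r, p in zip(uni["ref_id"], uni["pos"])]
    bg_pairs = [background.get(m) for m in motifs]
    bg = np.array([r for r, _ in bg_pairs])
    bg_fallback = [f for _, f in bg_pairs]

    ratio_cell = uni["ratio"].to_numpy(dtype=float)
    ratio_ivt = uni["ratio_ivt"].to_numpy(dtype=float)
    ratio_i2 = uni["ratio_input2"].to_numpy(dtype=float)
    depth_cell = uni["depth"].to_numpy(dtype=int)
    mis = uni["mis_count"].to_numpy(dtype=int)
    ct_denom = (mis + uni["n_T"].to_numpy(dtype=int) if cfg.ratio_mode == "tc"
                else depth_cell)

    p0 = ratio_ivt if cfg.binom_null == "ivt" else bg
    with np.errstate(invalid="ignore"):
        p_binom = np.where(
            mis == 0, 1.0,
            stats.binom.sf(np.maximum(mis - 1, 0), ct_denom, np.clip(p0, 0, 1)),
        )
    p_binom_adj = p_binom.copy()
    if cfg.multiple_testing == "bh":
        valid = ~np.isnan(p_binom)
        if valid.any():
            p_binom_adj[valid] = stats.false_discovery_control(p_binom[valid], method="bh")

    calls: list[SiteCall] = []
    for i, row in enumerate(uni.itertuples(index=False)):
        motif = motifs[i]
        flags: list[str] = []
        rt = ratio_cell[i] if not np.isnan(ratio_cell[i]) else None
        rv = ratio_ivt[i] if not np.isnan(ratio_ivt[i]) else None
        r2 = ratio_i2[i] if not np.isnan(ratio_i2[i]) else None
        if rt is None:
            flags.append("undefined_cell_ratio")
        if rv is None:
            flags.append("undefined_ivt_ratio")
        if r2 is None:
            flags.append("missing_input2")
        if bg_fallback[i]:
            flags.append("background_fallback")
        pt = p_ttest[i] if not np.isnan(p_ttest[i]) else None
        pb = p_binom_adj[i] if not np.isnan(p_binom_adj[i]) else None
        in_trna = trna_regions is not None and trna_regions.contains(row.ref_id, int(row.pos))

        crit: dict[str, bool] = {}
        crit["cell_ratio"] = rt is not None and rt > cfg.min_ratio_cell
        crit["ivt_ratio"] = rv is not None and rv < cfg.max_ratio_ivt
        crit["ivt_ttest_fold"] = (
            pt is not None and pt < cfg.max_p_ttest
            and rt is not None and rv is not None
            and rt > cfg.fold_over_ivt * max(rv, eps)
        )
        crit["not_trna"] = not in_trna
        crit["fold_background_input2"] = (
            rt is not None and r2 is not None
            and rt > cfg.fold_over_background * max(bg[i], eps)
            and rt > cfg.fold_over_input2 * max(r2, eps)
        )
        crit["depth"] = depth_cell[i] > cfg.min_depth_cell
        crit["not_multi_u"] = (
            not is_multi_u(motif, cfg.multi_u_mode) if cfg.exclude_multi_u else True
        )
        crit["binom"] = pb is not None and pb < cfg.max_p_binom

        called = all(crit.values())
        if not replicated:
            flags.append("provisional_single_replicate")
            called = False

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
            depth_treated=int(depth_cell[i]),
            ratio_treated=rt, ratio_input2=r2, ratio_ivt=rv,
            mis_count_treated=int(mis[i]),
            fold_background=None if rt is None else rt / max(bg[i], eps),
            fold_input2=None if (rt is None or r2 is None) else rt / max(r2, eps),
            fold_ivt=None if (rt is None or rv is None) else rt / max(rv, eps),
            p_ttest=pt, p_binom=pb,
            d_fraction=d_fraction, clamped=clamped,
            criteria=crit, called=called, flags=flags,
        ))
    return calls
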