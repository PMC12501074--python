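import numpy as np
import pandas as pd
import pytest

from craci.calibration import BackgroundTable, CalibrationCurve, CalibrationSet
from craci.io_formats import COUNT_COLUMNS


def count_row(ref_id="ref001", pos=10, strand="+", ref_base="T",
              n_A=0, n_C=0, n_G=0, n_T=0, n_del=0,
              sample_id="s", condition="treated", replicate=1) -> dict:
    return dict(ref_id=ref_id, pos=pos, strand=strand, ref_base=ref_base,
                n_A=n_A, n_C=n_C, n_G=n_G, n_T=n_T, n_del=n_del,
                sample_id=sample_id, condition=condition, replicate=replicate)


def count_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


@pytest.fixture
def flat_background() -> BackgroundTable:
    """Uniform 7% background across every motif (fallback-free)."""
    from craci.calibration import enumerate_motifs

    motifs = enumerate_motifs()
    return BackgroundTable(rates={m: 0.07 for m in motifs},
                           depths={m: 1000 for m in motifs})


@pytest.fixture
def unit_curves() -> CalibrationSet:
    """y = 0.9 x + 0.05 for every motif."""
    from craci.calibration import enumerate_motifs

    return CalibrationSet([
        CalibrationCurve(motif=m, slope_A=0.9, intercept_b=0.05, r2=1.0, n_points=6)
        for m in enumerate_motifs()
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_call_problem(seed: int, n_sites: int):
    """Randomized treated/input1/input2 tables over one random reference.

    Counts are drawn to straddle every caller threshold (ratios 0-0.5,
    depths 10-200, occasional missing input rows) so criterion logic is
    exercised on both sides of each bound. Returns
    (treated, input1, input2, reference_dict, BackgroundTable).
    """
    from craci.calibration import BackgroundTable, enumerate_motifs

    rng = np.random.default_rng(seed)
    length = n_sites * 8 + 20
    while True:
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
        t_pos = [i + 1 for i, c in enumerate(seq) if c == "T"][: n_sites]
        if len(t_pos) >= n_sites:
            break
        length = int(length * 1.5)

    def condition_rows(condition, max_ratio, p_missing):
        rows = []
        for rep in (1, 2):
            for pos in t_pos:
                if rng.random() < p_missing:
                    continue
                depth = int(rng.integers(10, 200))
                ratio = rng.uniform(0.0, max_ratio)
                n_c = int(rng.binomial(depth, ratio))
                rows.append(count_row(ref_id="ref", pos=pos, n_C=n_c,
                                      n_T=depth - n_c, condition=condition,
                                      replicate=rep))
        return count_frame(rows)

    treated = condition_rows("treated", 0.5, 0.0)
    input1 = condition_rows("input1", 0.25, 0.05)
    input2 = condition_rows("input2", 0.25, 0.05)
    bg = BackgroundTable(
        rates={m: float(r) for m, r in
               zip(enumerate_motifs(), np.random.default_rng(seed + 1).uniform(0.02, 0.15, 256))})
    return treated, input1, input2, {"ref": seq}, bg
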