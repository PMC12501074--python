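"""Call rare mRNA D sites against an in-vitro-transcribed background.

Simulates duplicate cellular and IVT libraries over a transcriptome-like
reference with three planted sites, then applies the eight-criterion
caller: cellular ratio > 20 %, IVT < 20 %, replicate t-test p < 0.05 with
3-fold over IVT, outside tRNA regions, 2-fold over background and Input2,
depth > 30, no multi-U context, and a binomial test against the motif
background.
"""

from craci import (
    BackgroundTable,
    CalibrationSet,
    SimConfig,
    call_sites_mrna,
    choose_sites,
    enumerate_motifs,
    simulate_counts,
)
from craci.calibration import CalibrationCurve

layout = dict(n_refs=4, ref_length=1500)
base = simulate_counts(SimConfig(seed=23, n_true_sites=0, replicates={}, **layout))
picks = choose_sites(base.reference, 3, (0.5, 0.5), seed=23)
truth = [(r, p, f) for (r, p, _), f in zip(picks, (0.25, 0.30, 0.40))]

sim = simulate_counts(SimConfig(seed=23, depth=300, truth=truth,
                                replicates={"treated": 2, "input2": 1, "ivt": 2},
                                **layout))
background = BackgroundTable(rates={m: 0.05 for m in enumerate_motifs()})
curves = CalibrationSet([CalibrationCurve(m, 0.9, 0.05) for m in enumerate_motifs()])

calls = call_sites_mrna(
    [sim.tables[("treated", 1)], sim.tables[("treated", 2)]],
    [sim.tables[("ivt", 1)], sim.tables[("ivt", 2)]],
    sim.tables[("input2", 1)], curves, background, None, sim.reference)

called = [c for c in calls if c.called]
print(f"site universe: {len(calls)} uridines covered in cell AND IVT; called {len(called)}\n")
print("ref      pos  ratio_cell  ratio_ivt   p_ttest   p_binom  est_fraction")
for c in called:
    print(f"{c.ref_id}  {c.pos:4d}  {c.ratio_treated:10.3f}  {c.ratio_ivt:9.3f}"
          f"  {c.p_ttest:8.2g}  {c.p_binom:8.2g}  {c.d_fraction:12.3f}")

print("\nPlanted fractions were 0.25 / 0.30 / 0.40; zero background uridines")
print("should pass all eight criteria.")
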