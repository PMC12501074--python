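"""Assign D sites to their writer enzymes from knockdown dynamics.

Simulates a control condition plus one dataset per dihydrouridine synthase
knockdown, where each knockdown zeroes the stoichiometry of its own target
sites. Sites are paired between conditions, deltas feed a paired t-test,
and each site is assigned to the writer whose depletion drops it most.
"""

from craci import (
    BackgroundTable,
    CalibrationSet,
    ConditionComparison,
    SimConfig,
    assign_writer,
    call_sites_ncrna,
    choose_sites,
    enumerate_motifs,
    paired_compare,
    simulate_counts,
)
from craci.calibration import CalibrationCurve

layout = dict(n_refs=3, ref_length=1000)
base = simulate_counts(SimConfig(seed=31, n_true_sites=0, replicates={}, **layout))
picks = choose_sites(base.reference, 8, (0.5, 0.9), seed=31)
writers = ("DUS1L", "DUS2L")
planted = {w: {(r, p) for r, p, _ in picks[i::2]} for i, w in enumerate(writers)}

background = BackgroundTable(rates={m: 0.05 for m in enumerate_motifs()})
curves = CalibrationSet([CalibrationCurve(m, 0.9, 0.05) for m in enumerate_motifs()])


def run(truth):
    sim = simulate_counts(SimConfig(seed=31, depth=500, truth=truth, **layout))
    return call_sites_ncrna(sim.tables[("treated", 1)], sim.tables[("input1", 1)],
                            sim.tables[("input2", 1)], curves, background,
                            sim.reference)


control = {c.site: c.d_fraction for c in run(list(picks)) if c.called}
comparisons = {}
for w in writers:
    kd_truth = [(r, p, 0.0 if (r, p) in planted[w] else f) for r, p, f in picks]
    kd = {c.site: c.d_fraction for c in run(kd_truth) if c.d_fraction is not None}
    comparisons[w] = [ConditionComparison(r, p, control[(r, p)], kd[(r, p)])
                      for (r, p) in sorted(control)]
    result = paired_compare(control, kd)
    print(f"{w} knockdown vs control: paired t p = {result.p_value:.3g} "
          f"over {len(result.comparisons)} shared sites")

assignments = assign_writer(comparisons, drop_threshold=0.10)
print("\nsite              assigned   drop   truth")
for site, a in sorted(assignments.items()):
    truth_w = next(w for w in writers if site in planted[w])
    print(f"{site[0]}:{site[1]:<6d}  {a.writer:9s}  {a.drop:.3f}  {truth_w}")

print("\nEach site should be assigned to the writer whose knockdown erased it;")
print("drops near the control stoichiometry confirm complete dependence.")
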