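"""Quantify black-carbon particles in synthetic leaf z-stacks.

Plants a known number of particles per stack, runs the projection →
threshold → connected-component pipeline, and compares locations with the
Kruskal–Wallis / pairwise Wilcoxon tests.
"""

from phyllo import StackConfig, compare_bc_groups, gen_bc_replicates, quantify_stack

# a small frame keeps this example quick; the defaults mirror the
# instrument's 900x900 um field at 1.8 um/px
template = StackConfig(width_px=128, height_px=128, n_slices=8)
stacks = gen_bc_replicates(
    {"Rural": 3.0, "Inner-city": 12.0, "Intersection": 20.0},
    template=template,
    seed=2,
)

metrics = {
    loc: [quantify_stack(stack) for stack, _truth in reps]
    for loc, reps in stacks.items()
}
for loc, ms in metrics.items():
    density = sum(m.particles_per_mm2 for m in ms) / len(ms)
    cover = sum(m.area_covered_percent for m in ms) / len(ms)
    print(f"{loc:13s} mean {density:8.1f} particles/mm^2, "
          f"{cover:.3f}% leaf area covered  ({len(ms)} replicates)")

report = compare_bc_groups(metrics)
print(f"\nKruskal-Wallis H = {report['kruskal_H']:.2f}, p = {report['kruskal_p']:.2e}")
for row in report["pairwise"]:
    print(f"  {row['a']} vs {row['b']}: Wilcoxon p = {row['p']:.4f} "
          f"(BH-adjusted {row['p_adj']:.4f})")
# Higher particle loads at trafficked sites should separate cleanly:
# small omnibus and pairwise p-values mean the location differences exceed
# replicate noise.
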