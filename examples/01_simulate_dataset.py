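"""Generate a synthetic phyllosphere dataset and inspect its design.

Builds the full sampling design — 3 sites × 2 years × 4 replicates — with
planted urban site effects, plus a phylogeny, and prints the design shape
and library-depth spread.
"""

from phyllo import CommunityConfig, gen_asv_table, gen_tree, urban_site_effects

genera = CommunityConfig().genus_ids()
effects = urban_site_effects(genera, magnitude=1.5, seed=1)
cfg = CommunityConfig(seed=1, site_effect_log2=effects)
table, taxonomy, truth = gen_asv_table(cfg)
tree = gen_tree(table.asv_ids, mode="random-coalescent", seed=1)

depths = table.sample_sums()
print(f"samples: {table.n_samples} "
      f"({cfg.n_sites} sites x {cfg.n_years} years x {cfg.n_replicates} replicates)")
print(f"ASVs: {len(table.asv_ids)} across {cfg.n_genera} genera")
print(f"library depths: {depths.min()}-{depths.max()} reads")
print(f"genera with planted urban effects: {sorted(effects)}")
print(f"tree tips: {tree.count(tips=True)}")
# The depth spread emulates the ~12-fold library-size range of real runs;
# the planted log2 effects are what the downstream tests try to recover.
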