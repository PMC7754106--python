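"""Pairwise LD from unphased genotypes and proxy-variant search.

A small simulated panel with block LD structure: variants in the causal
variant's haplotype block are strong proxies (r2 > 0.7), variants in other
blocks are not.
"""

from locuslens import SimConfig, find_proxies, ld_pair_report, simulate_panel

cfg = SimConfig(seed=7, n_samples=300, n_variants=30, block_size=10, copy_prob=0.95)
panel = simulate_panel(cfg)

target = panel.variant_ids[15]  # middle of the second block
stats = ld_pair_report(target, panel.variant_ids[16], panel)
print(
    f"{target} vs {panel.variant_ids[16]}: r2={stats.r2:.3f} D'={stats.d_prime:.3f} "
    f"(n={stats.n}, EM converged in {stats.n_iter} iterations)"
)

proxies = find_proxies(target, panel, r2_min=0.7)
print(f"{len(proxies)} proxies of {target} at r2 > 0.7:")
for vid, s in proxies:
    print(f"  {vid}: r2={s.r2:.3f} D'={s.d_prime:.3f}")

# with copy probability 0.95 the within-block neighbours exceed r2 = 0.7;
# all proxies come from the target's own 10-variant block.
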