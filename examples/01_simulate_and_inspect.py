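"""Generate a synthetic altitude-stratified cohort and inspect its variable sites.

Builds the reference conditions (8 altitude groups x 30 samples, 2000
positions, 20 planted perfectly co-occurring pairs, a control-region-like
hotspot) and prints each group's site summary.
"""

import math

from mtcooc import SynthConfig, extract_variable_sites, generate_cohort, site_statistics, toy_annotation

config = SynthConfig(seed=7)
cohort, manifest = generate_cohort(config)
annotation = toy_annotation(config.genome_length)

print(f"cohort: {cohort.n_samples} samples, {cohort.n_columns} aligned positions")
print(f"planted: {len(manifest.pairs)} pairs, {len(manifest.singletons)} singleton records")
print()
print("group  sites  coding  noncoding  Ts:Tv  triallelic")
for g in range(1, 9):
    sites = extract_variable_sites(cohort, g, annotation)
    st = site_statistics(sites, annotation)
    ratio = "inf" if math.isinf(st.ts_tv_ratio) else f"{st.ts_tv_ratio:.1f}"
    print(f"{g:>5}  {st.n_variable_sites:>5}  {st.n_coding:>6}  {st.n_noncoding:>9}"
          f"  {ratio:>5}  {st.n_triallelic:>10}")
print()
print("Ts:Tv scatters around 9 (the 90% transition bias typical of mtDNA);")
print("per-group ratios vary widely because each group sees only ~40 sites.")
print("The noncoding tally is dominated by the hypervariable CR-like block.")
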