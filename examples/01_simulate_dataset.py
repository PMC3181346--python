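"""Generate a synthetic two-process expression study with planted truth.

Builds the default dataset: a rat-like injury time course (cortex and
medulla; sham/6h/24h/120h, n=3) and a mouse-like developmental time course
(E16d/PN1d/PN7d, n=5), with 2 gene sets planted up and 2 down per
comparison and a 3-set "shared program" perturbed in both processes.
"""

from pagenet import SyntheticConfig, generate_catalog, generate_experiment_pair

config = SyntheticConfig(seed=1)
catalog = generate_catalog(config)
rat, mouse, omap, truth = generate_experiment_pair(config, catalog)

print(f"rat-like matrix:   {rat.n_genes} genes x {rat.n_samples} samples")
print(f"mouse-like matrix: {mouse.n_genes} genes x {mouse.n_samples} samples")
print(f"catalog: {len(catalog)} sets; ortholog pairs: {len(omap)}")
print(f"shared program (planted in both processes): {truth.shared_program}")
print(f"sets planted up at the injury peak (cortex): "
      f"{truth.expected_up('cortex_24h_vs_sham')}")
# The shared-program sets appear both up at 24h and down postnatally:
# that cross-process overlap is what the association network should find.
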