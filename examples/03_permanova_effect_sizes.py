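"""Partition beta diversity into body-site and host-species effects.

Sequential PERMANOVA on Bray-Curtis distances; partial omega-squared puts
the two factors' effect sizes on a comparable, bias-adjusted scale.
"""

from phylosym import (SimConfig, beta_matrix, permanova, simulate_dataset,
                      to_relative)

cfg = SimConfig(n_species=12, n_sites=3, samples_per_species_site=3,
                phi=0.6, seed=3)
host, table, metadata, _, _ = simulate_dataset(cfg)

dm = beta_matrix(to_relative(table), metric="bray_curtis")
res = permanova(dm, metadata.data, ["body_site", "host_species"],
                n_permutations=999, seed=1)
print(res.to_frame().round(4))

# omega2_partial is the share of distance-based variance attributable to a
# term after bias adjustment; permutation p-values test each pseudo-F.
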