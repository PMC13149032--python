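"""EVT density adjacent to vessel walls versus randomized decidual regions.

For each spiral-artery cross-section, the EVT density of its 100-px outer
annulus is compared with congruent annuli dropped at random into vessel-free
decidua; the pooled two-sided rank-sum test quantifies perivascular EVT
aggregation.
"""

from mfispatial import geometry, pipelines, vessels

section = pipelines.enriched_section(seed=0, n_vessels=62, n_evt=3000)
distances = geometry.compute_distances(section)
spec = vessels.RegionSpec(annulus_width_px=100.0, draws_per_vessel=10, seed=0)

obs = vessels.evt_density_near_vessels(section, distances, spec)
null = vessels.sample_null_regions(section, spec)
res = vessels.enrichment_test(obs["density"], null["density"])

print(f"vessels: {res.n_vessels}, null regions: {res.n_null}")
print(f"median vessel-annulus EVT density: {obs['density'].median():.2e} per px^2")
print(f"median null density:               {null['density'].median():.2e} per px^2")
print(f"two-sided rank-sum p = {res.pvalue:.3g}")
# The generator plants a 3x EVT density inside the perivascular zone, so the
# vessel annuli should be decisively denser than the randomized regions.
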