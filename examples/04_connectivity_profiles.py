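"""Build the three connectivity-profile types and verify their identities.

A region's full fine-grained profile correlates each of its vertices with
every cortical vertex; the coarse profile averages each region-pair block
into a single number; the residual profile subtracts those block means.
Fine = residual + expanded coarse, exactly, and regressing fine on the
expanded coarse always gives slope 1.
"""

import numpy as np

from fgconn.cohort import CohortConfig, make_parcellation, simulate_cohort
from fgconn.connectivity import expand_coarse, subject_profiles, vectorize_profile
from fgconn.preprocess import preprocess_subject

config = CohortConfig(family_histogram={1: 1}, n_vertices=60, n_regions=6,
                      n_timepoints_per_run=200, seed=8)
parcellation = make_parcellation(config.n_vertices, config.n_regions, seed=9)
subjects, _, _ = simulate_cohort(config, parcellation=parcellation)
ts = preprocess_subject(subjects[0])

region = 2
fine, coarse, residual = subject_profiles(ts, parcellation, region)
print(f"fine profile:     {fine.matrix.shape} "
      f"({vectorize_profile(fine).size} features)")
print(f"coarse profile:   {coarse.vector.shape} (one mean per region)")
print(f"residual profile: {residual.matrix.shape}")

expanded = expand_coarse(coarse, parcellation, fine.matrix.shape[0])
print(f"max |fine - (residual + coarse)|: "
      f"{np.max(np.abs(fine.matrix - residual.matrix - expanded)):.1e}")
slope = np.polyfit(expanded.ravel(), fine.matrix.ravel(), 1)[0]
print(f"OLS slope of fine on expanded coarse: {slope:.12f}")
block_means = [residual.matrix[:, parcellation.vertices_of(s)].mean()
               for s in range(parcellation.n_regions)]
print(f"residual block means: max |.| = {np.max(np.abs(block_means)):.1e}")
# The residual profile therefore carries purely fine-scale information,
# unconfounded by region-pair mean connectivity.
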