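# connlife

Multi-level analysis of resting-state functional brain networks over the
adult lifespan: how the connectivity architecture of canonical resting-state
networks (RSNs) reorganizes with age, and whether that reorganization is
associated with general cognitive performance.

The package is aimed at researchers analysing resting-state fMRI cohorts
with demographic and cognitive covariates. It implements the full analysis
chain downstream of spatial preprocessing — motion screening, nuisance
regression and band-pass filtering, dual regression against group RSN
templates, a spatial-similarity measure of network integrity, a
graph-theoretic battery over a 499-ROI whole-brain parcellation, network-level
connectivity summaries, and partial-correlation plus bootstrap-mediation
inference — together with a fully synthetic cohort generator with known
ground truth, so that every stage is testable without access to any
restricted imaging data.

## The measures

**Network integrity (η²).** The similarity of a subject-specific RSN map
*a* to a reference map *b* (the voxelwise mean map of a young-adult
subgroup, age ≤ 30 by default) is

```
η² = 1 − Σᵢ [(aᵢ − mᵢ)² + (bᵢ − mᵢ)²] / Σᵢ [(aᵢ − M̄)² + (bᵢ − M̄)²]
```

where `mᵢ = (aᵢ + bᵢ)/2`, `M̄` is the grand mean of *m*, and the sum runs
over the V voxels compared. η² ∈ [0, 1]; it equals 1 iff the maps are
identical and, unlike a correlation, it is sensitive to scale as well as
pattern.

**Motion screening.** Framewise displacement
`FDₜ = |Δx| + |Δy| + |Δz| + r(|Δα| + |Δβ| + |Δγ|)` with r = 50 mm; a subject
is excluded when mean FD ≥ 0.2 mm or more than 20% of volumes have
FD > 0.2 mm.

**Dual regression.** Stage 1 regresses each fMRI volume jointly on all K
group templates (giving K subject time courses); stage 2 regresses each
voxel's series jointly on those courses (giving K subject-specific maps).

**Graph battery.** Pearson connectivity over 499 nodes is binarized at
r ∈ {0.20, 0.25, 0.30, 0.35, 0.40}; per graph: characteristic path length,
global efficiency, mean degree, mean betweenness, Louvain modularity Q, and
the hierarchy exponent β of C(k) ∝ k^(−β).

**Network-level connectivity.** Correlations are Fisher-transformed
(z = atanh r); WNFC is the mean z over node pairs within one RSN, BNFC the
mean z over pairs straddling two RSNs, using the 142 RSN-assigned nodes.

**Mediation.** With age x, a connectivity measure M, cognition y (ACE-R
total, 0–100) and sex as covariate: `M = a·x + …`, `y = b·M + c′·x + …`,
`y = c·x + …`; the indirect effect ab = a·b = c − c′, with z and p per path
from subject-level bootstrap resampling (10,000 samples by default).

## Worked example

A 60-subject synthetic cohort with the default planted effects (declining
within-network coupling, age-increasing map dissimilarity, negative
indirect age effect on cognition):

```python
import numpy as np
from connlife import (
    CohortConfig, generate_cohort, generate_spatial_maps, make_templates,
    build_reference, similarity_table, partial_correlation,
    bootstrap_mediation, default_parcellation,
)

parc = default_parcellation()
cfg = CohortConfig(n_subjects=60, seed=7)
subjects, truth = generate_cohort(cfg)
age = np.array([s.age for s in subjects])
sex = np.array([s.sex for s in subjects], dtype=float)
ace = np.array([s.ace_r_total for s in subjects])

templates = make_templates(parc.rsn_networks, cfg.grid_shape, seed=7)
maps = {s.subject_id: generate_spatial_maps(s, truth, templates) for s in subjects}
ref = build_reference(maps, {s.subject_id: s.age for s in subjects}, cutoff_age=30)
eta = similarity_table(maps, ref).pivot(index="subject_id",
                                        columns="rsn_label", values="eta_sq")

res = partial_correlation(eta["visuospatial"].to_numpy(), age,
                          covariates=np.column_stack([sex, ace]))
print(f"visuospatial eta^2 vs age: r = {res.r:.3f}, p = {res.p:.2e}")

med = bootstrap_mediation(age, eta.mean(axis=1).to_numpy(), ace,
                          covariates=sex, n_boot=10_000, seed=7)
print(f"mediation age -> mean eta^2 -> ACE-R: ab = {med.ab:.4f} "
      f"(z = {med.z_per_path['ab']:.2f}, p = {med.p_per_path['ab']:.4f})")
```

Output:

```
visuospatial eta^2 vs age: r = -0.872, p = 5.03e-19
mediation age -> mean eta^2 -> ACE-R: ab = -0.0858 (z = -3.45, p = 0.0002)
```

The first line is the partial correlation (controlling sex and ACE-R)
between the visuospatial network's integrity and age: strongly negative,
because the generator plants a map-dissimilarity gradient with age. The
second line is the bootstrap indirect effect of age on cognition through
measured network integrity: negative and significant, matching the planted
mediation structure (in ACE-R points per standardized-age unit times the
η²-scaled path).

The same chain is available from the shell:

```bash
connlife run --config run.yaml     # simulate -> screen -> ... -> mediate
connlife screen --motion-dir motion/ --mean-fd 0.2 --frac 0.2
connlife parcellation              # validate the 499-ROI node counts
```

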