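# Methods

## The analysis in brief

`phmrinet` implements a voxel-scale complex-network analysis of
pharmacological MRI (phMRI) response maps. Each subject contributes a
single 3D map of response amplitude to an acute drug challenge; the data
for one cohort are therefore a node-by-subject matrix, one row per
in-mask voxel. Connectivity is defined **across subjects**, not across
time: the edge weight between voxels *i* and *j* is

    w_ij = |z_ij|,   z_ij = ½ ln((1 + r_ij) / (1 − r_ij)),

where `r_ij` is the Pearson correlation of the two voxels' response
amplitudes over the cohort. The complete weighted graph is reduced to a
binary one by **equi-sparse thresholding**: exactly the strongest
`round(s·N(N−1)/2)` edges are retained (default sparsity `s = 0.02`), so
networks from different cohorts share an edge count and differ only in
topology. On the binary network we compute per-node degree `k_i` and
clustering coefficient `c_i = 2·E(G_i)/(k_i(k_i−1))`, the global means
`K` and `C`, the characteristic path length `L`, the power-law slope of
the degree histogram, and the small-world indices

    γ = C / C_random,   σ_SW = (C / C_random) / (L / L_random),

with `C_random`, `L_random` means over an ensemble of 10 degree-preserving
(Maslov–Sneppen double-edge-swap) rewirings of the same network. Node
metrics are mapped back to voxel space, profiled per atlas region (VOI),
compared between each drug cohort and the vehicle (saline) cohort by
two-sided Mann–Whitney tests with Bonferroni correction, and classified
against vehicle-referenced percentile cutoffs into high-k / high-c /
high-k-and-c / low-c foci.

## Preprocessing

Maps are smoothed with an isotropic Gaussian kernel (default FWHM
0.6 mm; σ = FWHM/(2√(2 ln 2)) per axis in voxel units), zero-padded at
the boundary with the kernel truncated at 4σ, then rebinned in-plane by a
factor of 2 (block means; the slice axis is untouched). The mask is
rebinned by majority vote with ties counted in-mask; in-plane dimensions
not divisible by the factor are cropped with a warning. Node identifiers
follow raster order over in-mask voxels (x fastest, then y, then z,
0-based) and every writer records this convention.

Smoothing precedes rebinning; both precede masking. Correlations of ±1,
possible at small cohort sizes, are clipped to ±(1 − 1e−12) before the
Fisher transform — the weight stays finite and the rank order (all that
binarization consumes) is unchanged. Ties at the threshold weight are
broken lexicographically by (i, j) so the retained edge count is exact
and deterministic. An alternative `threshold_by_value` mode retains all
edges at or above a fixed weight for comparison with fixed-threshold
workflows; edge density then varies between cohorts.

## Null models and small-world indices

Each null realization applies `10·E` accepted double-edge swaps
(rejecting self-loops and duplicate edges), preserving the full degree
sequence exactly; the ensemble is deterministic given a seed. `C_random`
and `L_random` are ensemble means. For a K-regular graph the expected
clustering of such a null is the excess-degree (configuration-model)
value `(K−1)²/(KN)` — slightly below the coarse density estimate `K/N` —
and the test suite checks the rewired ring lattice against that form.
`L` is the mean shortest-path length over ordered pairs within the
largest connected component; a warning reports component sizes when the
network is disconnected, and another warns when `K ≤ ln N`, below which
topological properties of density-matched comparators are not reliably
estimable.

## Degree histograms and the power-law fit

`degree_histogram` supports factor-2 logarithmic bins (display default)
and unit-width linear bins; bin centers are the mean degree of the bin's
members and empty bins are dropped, so counts always sum to N. The
power-law slope is the least-squares slope of log10(count) on
log10(center) over nonzero bins in a user-set window. Note the binning
matters: for a degree density `∝ k^(−γ)`, linear bins recover −γ while
factor-2 log bins recover −(γ−1), because log-bin width grows `∝ k`. The
exponent-recovery test therefore uses linear bins.

## VOI statistics, cutoffs and foci

Mann–Whitney tests are two-sided with the direction of the median shift
reported separately. For group sizes ≤ 8 with tie-free data the exact
distribution is enumerated; otherwise the normal approximation with
continuity and tie corrections is used. The Bonferroni family is the
number of VOIs tested per metric per drug-vs-vehicle comparison, recorded
in the output (`m_family`). Significance tiers follow corrected p:
+/− below 0.05, ++/−− below 0.01, +++/−−− below 0.001. Nodes within a
VOI are treated as independent observations; smoothing-induced spatial
dependence makes the tests anticonservative at the region level, a caveat
inherited from the design rather than corrected here.

Cutoffs are the 95th percentile of vehicle `k` and the 2.5th/97.5th
percentiles of vehicle `c`, by linear interpolation between order
statistics; a constant clustering vector makes the cutoffs degenerate and
raises an error, and fewer than 20 vehicle nodes triggers a stability
warning. Foci labels: high_k if `k > k_high`, high_c if `c > c_high`,
both → high_k_and_c; low_c (`c < c_low`) applies only when neither high
label does.

## The synthetic cohort generator

Real phMRI cohorts are small (the study sizes 17/7/9/7 are the defaults)
and the raw data are not deposited, so every downstream stage is
exercised on synthetic cohorts with planted covariance. The model: an
atlas partitions an ellipsoidal "brain" into contiguous regions grown by
seeded accretion (unequal seeded growth rates emulate the unequal volumes
of anatomical structures); each region has a latent per-subject factor
drawn from a zero-mean multivariate normal with a specified cross-region
correlation matrix; each in-mask voxel's amplitude is
`loading · factor + noise_sd · ε` with independent standard-normal noise.
Latent factors and noise are normal because Pearson/Fisher machinery
assumes approximately normal amplitudes. The population inter-subject
correlation between voxels in regions p and q is

    ρ_pq = L_p L_q R_pq / √((L_p² + s²)(L_q² + s²)),

which the calibration test verifies by simulation at 500 subjects.

The atlas is defined at the **analysis** grid (default 26×26×8,
0.6×0.6×0.3 mm voxels, ≈1800 in-mask nodes) and upsampled ×2 in-plane to
the simulation grid, exactly as template-space VOI atlases sit at analysis
resolution; rebin blocks then never straddle region boundaries. Regions
with dorsal centroids are flagged cortical.

Frozen study conditions, and why:

- **Baseline (vehicle-like) covariance** — loadings on a quadratic ramp
  over [0.02, 0.1] (permuted across regions), uniform cross-region
  correlation 0.1, `noise_sd = 0.7`. Baseline structure sits far below
  the 2% retention threshold: the control network's edges are then
  dominated by sampling noise and smoothing-induced local correlation,
  with no region-level common factor near the threshold. This mirrors a
  control network whose anatomical structure is only slight, and it
  matters statistically: a region whose population correlation sits near
  the retention threshold fluctuates coherently with the subject draw,
  and the node-level Mann–Whitney test (nodes treated as independent)
  converts those common-factor swings into spurious extreme tiers.
- **Planted drug effect** — one region's loading raised to 0.95 with
  correlation 0.6 to three partner regions. The planting site is the
  largest region not exceeding 8% of the brain volume: a strongly loaded
  region forms a near-complete clique, so its degree scales with its
  size, and the cap keeps the whole region inside the top decile of k.
- **Size-matched comparison** — the planted drug cohort has 7 subjects,
  matching the vehicle cohort. Cohort-size asymmetry alone changes how
  equi-sparse edges are allocated (smaller sampling noise concentrates
  edges in the strongest background regions), which would confound the
  planted-effect readout.
- **Heavy-tailed regime** — for scale-free degree distributions the
  generator uses many regions (40) with Pareto(1.2) growth weights and a
  uniform moderate loading (0.6): hub degree scales with region volume,
  so power-law volumes yield a monotonically decaying degree histogram
  over more than a decade, with the finite-size pile-up at the largest
  clique sizes mirroring the high-k cutoff seen in real voxel networks.

What the generator does **not** emulate: spatially varying noise,
inter-subject registration error, physiological or scanner artifacts,
non-normal amplitude distributions, and within-region loading gradients.
Passing tests demonstrate that the pipeline recovers structure a block
covariance model plants at realistic cohort sizes — not that real phMRI
networks have that structure.

## Problem sizes and numerical choices

Synthetic studies run at ≈1800 nodes after rebinning (52×52×8 simulation
grid), where the 2% networks have K ≈ 36 ≥ ln N and correlation matrices
and all-pairs BFS are comfortably in memory; benchmark graphs use
N = 1000 (ring lattices, random graphs) and 10 null realizations, the
ensemble size used throughout. The planted-recovery check runs 20 seeded
replicates. Percentile interpolation is linear; `round()` on the edge
count rounds half away from zero; clustering for `k < 2` is defined as 0
so `C` averages over all nodes.

## Known limitations

- Inter-subject correlation networks at n = 7–17 subjects are extremely
  noisy at the edge level; only aggregate topology is interpretable, and
  the synthetic conditions were chosen so that planted aggregate effects
  are recoverable, not so that individual edges are.
- The Mann–Whitney VOI comparison treats nodes as independent (see
  above); its p-values are calibrated only under the baseline noise-floor
  conditions.
- Table-scale global parameters (e.g. mean degree at N = 8130) follow
  from the equi-sparsity arithmetic, but cohort-specific values from the
  original study data are not reproducible without those data.
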