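# phmrinet

Voxel-scale complex-network analysis of pharmacological MRI (phMRI)
response maps: inter-subject correlation networks, equi-sparse
binarization, graph-topology metrics with degree-preserving rewired null
models, region-of-interest statistics against a vehicle (saline) control,
and vehicle-referenced maps of high-degree / high-clustering foci.

It is written for imaging groups who have one response-amplitude map per
subject per pharmacological condition — too few time points for
conventional time-series functional connectivity — and want to analyse
the brain's drug response as a graph. Edges are defined **across
subjects**: the weight between voxels *i* and *j* is

    w_ij = |z_ij|,   z_ij = ½ ln((1 + r_ij)/(1 − r_ij)),

the Fisher-transformed Pearson correlation of the two voxels' response
amplitudes over the cohort. Each cohort's weighted complete graph is
binarized by retaining exactly the strongest 2% of the N(N−1)/2 possible
edges, so all cohorts share an edge count ("equi-sparse") and differ only
in topology. The package computes, per node, degree `k` and clustering
coefficient `c`, and per network the mean degree `K`, mean clustering
`C`, characteristic path length `L`, degree-histogram power-law slope,
and the small-world indices `γ = C/C_random` and
`σ_SW = (C/C_random)/(L/L_random)` against an ensemble of 10
Maslov–Sneppen rewirings. Node metrics are profiled per VOI, compared
drug-vs-vehicle with Bonferroni-corrected Mann–Whitney tests, and
classified against vehicle percentile cutoffs (95th of `k`, 2.5th/97.5th
of `c`) into high-k / high-c / conjunction / low-c foci.

Because real phMRI cohorts of this kind are small (17/7/9/7 subjects in
the motivating design) and rarely shareable, the package ships a
first-class synthetic cohort generator: an ellipsoidal "brain" with a
contiguous region atlas and a block covariance model (per-region latent
factors, cross-region coupling, voxel noise) whose planted effects the
full pipeline provably recovers. See `docs/methods.md` for the model and
all frozen parameter choices.

## Worked example

Simulate the four-cohort study (three "drugs", one vehicle; a focal
effect planted in one region per drug), build the 2%-sparse networks and
compare a drug to vehicle:

```python
from phmrinet import RunConfig, simulate_study, build_network
from phmrinet import node_metrics, global_summary, compare_voi

cfg = RunConfig(seed=1)
atlas, cohorts, planted = simulate_study(cfg)   # planted: {'drug_b': 2, ...}
rm, wn, bn = build_network(cohorts["drug_b"], cfg)
_, _, bn_veh = build_network(cohorts["vehicle"], cfg)

gm = global_summary(bn, n_null=10, seed=78)
print(f"N={gm.n_nodes} E={gm.n_edges} K={gm.K:.2f} C={gm.C:.3f} "
      f"L={gm.L:.2f} gamma={gm.gamma:.2f} sigma_SW={gm.sigma_SW:.2f}")

table = compare_voi(node_metrics(bn), node_metrics(bn_veh), atlas, metric="k")
cols = ["voi", "name", "median_drug", "median_vehicle", "tier"]
print(table[cols].to_string(index=False))
```

This prints

```
N=1792 E=32095 K=35.82 C=0.399 L=3.66 gamma=2.80 sigma_SW=1.83
 voi          name  median_drug  median_vehicle tier
   1 sub_region_01         19.0            36.0  ---
   2 ctx_region_02        180.0            36.0  +++
   ...
```

Region 2 — where the drug effect was planted — shows a median degree of
180 against 36 in the vehicle network and earns the strongest tier
(`+++`, Bonferroni-corrected p < 0.001), while the unplanted regions drop
slightly below vehicle (`---`): under equi-sparse thresholding the
planted clique absorbs edge budget from everywhere else, exactly the
trade-off the method is designed to expose. `gamma = 2.80` says the
network is almost three times as clustered as its degree-preserving
rewirings.

The same workflow is available from the shell:

```bash
phmrinet run --seed 1 --out results/study      # full pipeline + manifest
phmrinet simulate --seed 1 --out sim           # cohorts + atlas as NIfTI
phmrinet build --maps sim/drug_b/maps.nii.gz --mask sim/drug_b/mask.nii.gz --out net
phmrinet metrics --network net --out met
phmrinet sweep --seed 1 --out sweep            # threshold robustness
```

Every run writes a `manifest.json` with all parameters, seeds and file
checksums; two runs with the same config are bit-identical.

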