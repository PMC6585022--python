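# paralogon2r

Phylogenetic tests of the 2R whole-genome-duplication (WGD) hypothesis on
the human tetra-paralogon Hsa 1/2/8/20.

Vertebrate genomes carry sets of chromosomal regions — *paralogons* — in
which many unrelated gene families have paralogous copies. Under Ohno's 2R
hypothesis these arose from two rounds of whole-genome duplication early in
vertebrate history; the alternative is an accumulation of independent
small-scale (segmental) duplications spread over animal evolution. The two
histories make different predictions: 2R puts every family's duplications
into the same narrow window on the vertebrate stem with congruent tree
topologies, while independent duplications scatter in time and branching
pattern. This package implements the analysis chain used to discriminate
them for multigene families with three- or four-fold representation on
human chromosomes 1, 2, 8 and 20:

1. **Catalog census** (`catalog`): families classified by *fold* — the
   number of distinct target chromosomes hit by their members.
2. **Alignment preparation** (`msa`): complete deletion — every column
   containing a gap or missing datum (`X`) is removed.
3. **Tree inference** (`trees`): neighbor joining (Saitou–Nei) on the
   uncorrected amino-acid p-distance, `p(i,j) = #differing sites / length`
   (a Poisson correction, `d = −ln(1 − p)`, is available), bootstrap
   support from column resampling, outgroup rooting, and screening of
   leaves whose placement contradicts the conventional animal phylogeny.
4. **Duplication dating** (`duplications`): an internal node of a rooted
   gene tree is a duplication iff its child subtrees share a species
   (species-overlap rule). Each duplication is dated *ordinally* into an
   epoch bin bounded by named speciation splits of a fixed 46-taxon
   metazoan reference tree: **B1** before the invertebrate–vertebrate
   split, **B2** on the vertebrate stem (before the teleost–tetrapod
   split — the proposed 2R window), **B3** teleost-specific, **B4**
   tetrapod-specific.
5. **Topology congruence** (`congruence`): each family with ≥2 window
   duplications is collapsed to a *schematic topology* — a tiny rooted
   tree whose leaves are the human chromosomes carrying its paralogs. The
   *translocation distance* between two schematics is the minimum number
   of leaf relabelings (assumed translocations) making them isomorphic;
   physically linked families whose distance is within an allowance *k*
   cluster into **co-duplicated groups**.
6. **Synthetic data** (`simulate`): gene families generated under a clean
   two-round-WGD scenario or independent small-scale duplications with
   known event times, chromosome labels and co-duplication partition, so
   the whole chain is testable end to end.

## Worked example

The numbered drivers under `analysis/` reproduce the main results and
write tables under `results/`:

```
$ python analysis/01_catalog_census.py
25 families, 125 genes (100 on Hsa 1/2/8/20)
quadruplicated: 3, triplicated: 22
quadruplicated families: CHRN, E2F, FAM110

$ python analysis/04_coduplication_groups.py
16 families -> 4 co-duplicated groups
  G1 (symmetric, consensus ((1,2),(20,8)); allowance 5): DLGAP, HCK, KCNQ, MATN, NKAIN
  G2 (asymmetric, consensus ((1,6),20); allowance 2): E2F, EYA, STMN
  G3 (asymmetric, consensus ((20,8),2); allowance 4): FAM110, KCNS, MYT, NCOA, XKR, YTHDF
  G4 (asymmetric, consensus ((1,20),8); allowance 3): MROH, STK
MROH vs STK translocation distance: 3

$ python analysis/03_simulation_recovery.py
independent_SD: epoch-bin recovery 96.2% (231/240 events), mean ARI 1.00, ...
two_round_WGD: epoch-bin recovery 99.2% (357/360 events), mean ARI 0.85, ...
```

The catalog census is the packaged 25-family, 125-gene table; three
families reach all four target chromosomes. Clustering the schematic
panel yields four distinct co-duplicated groups — three asymmetric and
one symmetric `((A,B),(C,D))` — e.g. MROH `((20,1),8)` and STK
`((2,13),X)` join at translocation distance 3. In the simulation study
the pipeline recovers ≥ 96% of duplication events into their true epoch
bin and reconstructs the true co-duplication partition with adjusted Rand
index ≥ 0.85 under both scenarios.

A CLI exposes the same steps (`paralogon2r catalog summarize`,
`prep trim`, `tree build`, `dups infer`, `congruence group`, `simulate`,
`run`).

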