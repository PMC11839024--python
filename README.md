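# endonet

A pipeline for building an organelle structural interactome from
complementary proteomics evidence, centered on the early endosome. It
covers five stages, each usable on its own:

1. **Meta-analysis scoring** — candidate endosomal proteins are scored by
   three metrics: presence across independent organelle-proteome datasets,
   abundance in organelle affinity purifications (Endo-IP), and the number
   of interactions with well-known endosomal proteins. Each metric is
   evaluated by ROC against a curated reference list; the combined score is
   their (rank-normalized) sum, thresholded at a 10% false-positive rate on
   the reference negatives, with exclusion-list vetoes (e.g. mitochondrial
   annotation).
2. **Blue-native co-fractionation (BN-MS)** — intact complexes co-migrate
   through a native gel, so subunits share 48-fraction elution profiles.
   Candidate pairs pass when their co-elution score is ≥ 0.7 in ≥ 2
   replicates, the complex has ≤ 25 proteins, and the complex peak elutes
   at an apparent mass ≥ 67 kDa.
3. **Cross-linking MS (XL-MS)** — residue-pair cross-links (DSSO Lys–Lys;
   DHSO acid–acid; DMTMM acid–Lys) are deduplicated with a strict score
   cut (> 40), checked for membrane-topology consistency, and collapsed to
   protein-pair interactions; secondary chemistries are mapped onto the
   DSSO-defined interaction set through peptide ambiguity groups.
4. **Network integration** — XL and BN edges merge into an undirected
   graph; contaminants are blocklisted, the network is centered on the
   reference endosomal proteome (second-order interactors need ≥ 1
   cross-link edge or ≥ 2 BN edges to direct interactors), and the core
   component is characterized (mean shortest path, power-law R²,
   edge-betweenness communities, 100 degree-preserving rewiring
   permutations as null, 3-clique enumeration for trimer prediction).
5. **Structure triage and variants** — cross-linked residues are mapped
   onto Cα-level structural models; a link is satisfied when the Cα–Cα
   distance is ≤ 35 Å (standard predictions and experimental structures)
   or ≤ 30 Å (link-assisted predictions), gated on both residues having
   pLDDT > 70. Predictions are classified by SPOC score (> 0.33) and the
   majority status of their interprotein links; trimers need ≥ 2 interface
   averages > 0.5. Disease variants are flagged when they fall within 2
   residues of a predicted interface contact.

Every stage runs on synthetic fixtures with planted ground truth (the
`synthetic` module generates all six input kinds), so the complete chain
is testable without any external download.

## Worked example

The numbered drivers under `analysis/` run the stages in order and write
their tables under `results/`. For example:

```text
$ python analysis/02_meta_proteome.py
combined AUC 0.932 (best single 0.953); threshold 2.105 -> 156 predicted,
union with reference 170, realized FP rate 0.100

$ python analysis/05_network.py
network 129 nodes / 272 edges; core 129/272; 17 communities; 243 3-cliques;
within-complex mean distance 1.00 vs between 12.08 (p=0.010)

$ python analysis/06_structures_variants.py
4 models: categories {'supported': 2, 'low-confidence': 2}; inter-link
within-fraction [0.67, 0.67, 0.67, 0.67]; 12/24 variants near interfaces
(24/24 agree with planted truth)
```

Reading these: the meta-analysis calls 156 proteins endosomal at exactly
the 10% false-positive budget and unions them with the curated reference
for a 170-protein target proteome. The integrated synthetic network keeps
members of the same planted complex in direct contact (mean within-complex
path distance 1.0 vs 12.1 between complexes; empirical p = 0.01 against
100 degree-preserving rewired nulls). On the structural side, models with
SPOC above 0.33 whose planted links mostly satisfy the 35 Å constraint are
classified `supported`, and every planted near-interface variant is
recovered at the 2-residue window.

The same chain is available as a CLI:

```bash
endonet all --synthetic --seed 1 --outdir results/full_run
endonet xl results/synthetic_inputs/crosslinks.tsv
```

## Layout

- `src/endonet/` — the library: `synthetic`, `meta`, `cofrac`, `xltable`,
  `network`, `structure`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers (simulate → meta → BN → XL →
  network → structures → report).
- `tests/` — unit, property, and acceptance suites.
- `docs/methods.md` — model assumptions, parameter defaults, numerical
  choices, and known limitations.
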