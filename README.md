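# dicer-ruler

Structural analysis of the "molecular ruler" of Dicer-2, the insect RNase III
endonuclease that dices long double-stranded RNA into short interfering RNAs
(siRNAs) for antiviral RNA interference. The enzyme's PAZ domain anchors the
dsRNA terminus in two pockets (one for the 3′ overhang, one for the 5′
phosphate) while the tandem RNase III domains (A and B) cleave the duplex one
strand each; the spatial separation between anchoring pockets and catalytic
centers acts as a caliper that sets the product length. Different insect
lineages produce predominantly 20-, 21- or 22-nt siRNAs, and this package
quantifies the geometric hypothesis behind that variation.

It is aimed at structural bioinformaticians comparing Dicer-like orthologs:
given structures in PDB format and tables of functional-site residues, it
superimposes structures, transfers site annotations between orthologs by
sequence alignment, measures the caliper, and predicts siRNA length classes.

## The measurement

For a structure with annotated sites, the ruler is the pair of Euclidean
distances between unweighted Cα centroids,

```
d₃ = ‖ c(pocket 3′) − c(RNase III A) ‖ ,   d₅ = ‖ c(pocket 5′) − c(RNase III B) ‖ ,
```

summarized by their mean d̄ = (d₃ + d₅)/2. A calibration model anchored on a
reference enzyme of known product length L_ref at distance d_ref converts
distance to nucleotides:

```
L(d̄) = L_ref + round( (d̄ − d_ref) / rise ) ,
```

with a default pitch of rise = 2.0 Å per nucleotide (the crystallographic
A-form helical rise, 2.81 Å/bp, is available as an alternative; both give the
same length classes on the shipped ortholog data). An ordinary least-squares
fit of length on distance is available as a second calibration mode.
Differences in caliper spacing exceeding 0.5 Å are flagged as biologically
relevant; shifts of ±1–2 Å correspond to roughly 1–2 nt of product length.

Other pieces: Kabsch (SVD) superposition with global and per-domain RMSD,
pairwise global sequence alignment (affine gaps, BLOSUM62) for transferring
site annotations to orthologs, a PDB reader/writer that preserves author
residue numbering, and seeded generators of synthetic "caliper" scaffolds
and ideal A-form-like duplexes with known ground-truth geometry. The
packaged `table1_sites.tsv` lists the catalytic and pocket residues of five
insect Dicer-2 orthologs (*D. melanogaster* reference, *T. castaneum*,
*B. terrestris*, *L. migratoria*, *T. ni*).

## Worked example

Generate one synthetic scaffold per ortholog with that species' published
pocket-to-center distances, then run the pipeline (the `ruler` console
script; see `tests/conftest.py` for the same workspace built in code):

```sh
ruler synth scaffold --id dmel --d3p 61.0 --d5p 59.6 --seed 100 --out dmel
ruler synth scaffold --id tcas --d3p 58.8 --d5p 61.2 --seed 101 --out tcas
# ... bter (61.7, 62.7), lmig (63.7, 60.9), tni (53.6, 63.1)
ruler run --config config.yaml
```

prints (stderr warning omitted from the table):

```
WARNING dicer_ruler: target tcas: reported mean 59.8 Å disagrees with recomputed 60.0 Å
structure_id  d_RIIIA_3p  d_RIIIB_5p  mean  sd   predicted_nt  significant
dmel          61.0        59.6        60.3  0.0  21            false
tcas          58.8        61.2        60.0  0.0  21            false
bter          61.7        62.7        62.2  0.0  22            true
lmig          63.7        60.9        62.3  0.0  22            true
tni           53.6        63.1        58.3  0.0  20            true
```

Reading the output: the mean caliper distance of the reference (60.3 Å)
anchors the model at 21 nt; *B. terrestris* and *L. migratoria* sit ~2 Å
wider and are predicted to dice 22-nt siRNAs, *T. ni* ~2 Å narrower at
20 nt, and *T. castaneum* stays in the 21-nt class — matching the length
distributions observed experimentally in these lineages. The `significant`
column flags caliper shifts larger than 0.5 Å. The recomputed *T. castaneum*
mean is 60.0 Å; the configured reported value (59.8) is internally
inconsistent with its own distance pair, which the pipeline warns about
rather than reproduces. `sd` is the replicate standard deviation — exactly 0
here because the three replicates re-measure an unperturbed structure
(`perturb_sigma: 0`).

One structure at a time, without a config:

```sh
ruler measure --structure bter.pdb --sites bter.sites.tsv \
    --ref-distance 60.3 --ref-length 21
```

```json
{"structure_id": "bter", "mean_distance_1dp": 62.2, "predicted_nt": 22, ...}
```

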