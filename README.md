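# enzymespace

Tools for building a **structural coverage map of functional enzyme space**:
given EC-annotated protein sequences and structural models that carry a
per-residue quality score in the PDB B-factor column, the package clusters the
sequences into homologous families, purifies each cluster to a single EC
subsub-class, selects representatives, removes low-confidence terminal tails
from multi-domain models, categorizes binding-site buriedness, harmonizes
quality scores across model sources, and exports the result as a treemap plus
a flat metadata CSV.

It is aimed at structural bioinformaticians who want to chart which enzyme
functions (in the Enzyme Commission hierarchy) are covered by structural
models, and at what quality — at desk scale, with every input either real
files or generated synthetically by the built-in simulators.

## What it computes

**EC hierarchy.** An EC number `c1.c2.c3.c4` encodes main class, subclass,
subsub-class and the serial designation of the specific enzyme function; the
three-level prefix `c1.c2.c3` (the *subsub-class key*) is the unit of
functional purity throughout.

**Clustering.** Sequences are clustered greedily (longest first, CD-HIT
style): a sequence joins the first cluster whose representative it matches at
identity ≥ 30%, where identity comes from a global affine-gap
Needleman–Wunsch alignment,

    identity = identical aligned pairs / alignment columns
               (terminal-gap columns stripped)

with match +1, mismatch 0, gap open −5, gap extend −1. Clusters mixing
subsub-classes are split so each output cluster is pure, guaranteeing a
representative per subsub-class function; representatives are centroids by
mean identity.

**Terminal-disorder trimming.** A candidate unmodeled region (a contiguous
run of residues with quality score ≥ 0.6, or a caller-supplied mask) is
removed iff it (i) has ≥ 10 residues, (ii) contains no helix/strand element
longer than 5 residues, (iii) has median relative SASA > 0.40, (iv) has
median contact density < 4, and (v) is N- or C-terminal. SASA is computed by
Shrake–Rupley point sampling, relative SASA uses the Tien et al. (2013)
theoretical maxima, contacts are Cβ pairs within 8 Å at sequence separation
≥ 3, and secondary structure comes from Cα-only P-SEA-style windows.

**Binding-site buriedness.** Solvent grid points near a binding site are
scanned along 7 directions (3 axes + 4 cube diagonals); the degree of
buriedness (DOB, 0–7) of a point counts directions blocked by protein on both
sides. Sites with mean DOB ≥ 4 are `buried`; surface sites split into
`surface_noncomplete` (the homologous template assembly shows a complementary
surface missing from the model) and `surface` (no such information).

**Quality harmonization.** TopScore (0–1, lower better), pLDDT (0–100,
higher better) and QMEAN6 (~0–1) are mapped to one 0–1 higher-is-better
scale via `1 − TopScore`, `pLDDT/100`, and clamping. TopScore bands:
high < 0.2 ≤ good < 0.4 ≤ low.

## Worked example

```python
from enzymespace import synth, greedy_cluster, split_all, trim_structure
from enzymespace.quality import harmonize_score, quality_class

study = synth.make_study_set(seed=11)          # 25 records, 5 families
records = {r.accession: r for r in study["records"]}
clusters = split_all(greedy_cluster(list(records.values())), records)
print(f"{len(records)} records -> {len(clusters)} subsub-class-pure clusters")
for c in clusters:
    print(f"  {c.subsub_class:10s} rep={c.representative}  members={len(c)}")

trimmed, reports = trim_structure(study["structure"])
print(f"trimming: {study['structure'].n_residues} -> {trimmed.n_residues} residues")
```

prints

```
25 records -> 6 subsub-class-pure clusters
  6.3.2      rep=LIG000  members=2
  3.4.21     rep=PEP000  members=4
  2.3.1      rep=ACT000  members=5
  1.1.1      rep=ADH000  members=6
  3.6.1      rep=GTP003  members=1
  3.6.5      rep=GTP007  members=8
trimming: 42 -> 30 residues
```

Five greedy clusters (one per family) become six pure clusters because one
GTPase family member is bifunctional (`3.6.5.2;3.6.1.1`) and is attached to
both subsub-class clusters. The example model's 12-residue low-confidence
N-terminal coil satisfies all five removal criteria and is trimmed; the
30-residue confident helix body is kept.

The same steps are available from the shell:

```sh
enzymespace simulate --seed 11 --out-dir fixtures/
enzymespace cluster --records fixtures/records.json --out clusters.tsv
enzymespace trim fixtures/model_with_tail.pdb --out trimmed.pdb --report report.json
enzymespace treemap --records fixtures/records.json --clusters clusters.tsv \
    --out-csv metadata.csv --out-html map.html
```

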