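# Methods

This note records the models, conventions and numerical choices behind each
stage of the toolkit, what the synthetic generators emulate, and where the
design was genuinely open.

## EC hierarchy model

EC numbers are four dot-separated levels: main class (integer 1–7), subclass,
subsub-class, and the serial designation of the specific function. Deeper
levels may be wildcards (`-`), and the designation may be preliminary
(`n3`). A wildcard at one level forces wildcards below it; parsing is
lossless and `str(parse_ec(s))` returns the canonical 4-token form.

Count trees attach each EC label at its deepest concrete level and increment
every ancestor. A record carrying *k* EC numbers is counted once per label —
so a bifunctional enzyme contributes to two subtrees, and after cluster
splitting it can sit in one cluster per subsub-class. This double-attachment
rule is our choice; it is the simplest bookkeeping that preserves "one
representative per subsub-class function" for multifunctional enzymes.

## Sequence identity and clustering

*Alignment.* Global Needleman–Wunsch with affine gaps (Gotoh's three-state
recursion), scoring match +1, mismatch 0, gap open −5, gap extend −1 (a gap
of length L costs −5 − (L−1)). The traceback is made deterministic by the
fixed state preference match > gap-in-second-sequence > gap-in-first, so
identical inputs always yield the same alignment. Identity is *identical
aligned pairs / alignment columns after stripping terminal-gap columns*; the
stripping keeps a short sequence aligned inside a longer one from being
penalized for the overhang. Symmetry is enforced by always aligning the
(longer, lexicographically larger) sequence first. The affine aligner is
implemented in-repo because the identity denominator and tie-breaking are
load-bearing for reproducibility; the test suite cross-checks its scores
against an independent aligner.

*Greedy clustering.* Records are sorted by descending length (accession as
tie-break); each joins the first cluster whose representative it matches at
≥ the cutoff (default 0.30), else founds a cluster. This is the CD-HIT
scheme: representative-only comparisons, O(n·k) alignments. It is intended
for desk scale (≤10⁴ sequences); no k-mer prefilter is attempted. An
externally produced representative/member TSV can be loaded as a drop-in
replacement.

*Purity splitting.* A cluster whose members span several subsub-class keys
is partitioned by key; a multi-EC member joins every matching partition;
members with only wildcard subsub levels go to an `unclassified` partition
and never represent an EC-keyed cluster. Each partition's representative is
the centroid — the member maximizing mean identity to co-members, ties to
the longer sequence, then the smallest accession. The centroid rule is a
design choice (no published rule exists for this step); it is stable and
favors centrally placed sequences.

## Structure model and the score-in-B-factor convention

Structural models store one quality score per residue in the PDB B-factor
column. The internal convention is TopScore-like: 0–1, lower is better.
AlphaFold-style files (pLDDT, 0–100, higher better) are converted on input
via `1 − pLDDT/100`, forced by the requirement that a single internal scale
exist. Atoms of one residue must agree on the B-factor; disagreement is
tolerated with a warning and the mean. Only the first MODEL of multi-model
files is read (models here are single-conformer predictions); for alternate
locations the highest-occupancy atom is kept. Parsing and fixed-column
serialization (coordinates %.3f, B-factor %.2f) are delegated to biotite;
coordinate overflow of the fixed columns is refused before writing. mmCIF is
out of scope.

## Per-residue descriptors

*SASA.* Shrake–Rupley: 960 quasi-uniform golden-spiral points per atom on
the solvent-expanded sphere (probe 1.4 Å); the accessible fraction times
4π(r+p)² is the atom's area, residues sum their atoms. Van der Waals radii:
C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å; unknown elements fall back
to 1.70 Å with a warning (an error in strict mode). At 960 points the
isolated-sphere error is below 0.5% and random small clusters agree with a
Monte-Carlo sampler within 2%.

*Relative SASA* divides by the residue type's theoretical maximum from the
Tien et al. 2013 table. Values can exceed 1 at termini, which expose more
area than the Gly-X-Gly reference context. The table is configurable; no
particular normalization is canonical in the literature, so one is pinned
for reproducibility.

*Contact density* counts residues whose Cβ (Cα for Gly) lies within 8.0 Å,
requiring sequence separation ≥ 3 within a chain (inter-chain pairs always
eligible). Cutoff, anchor atom and separation are configurable; the 8 Å/Cβ
convention is the standard contact-map definition.

*Secondary structure* uses Cα-only P-SEA-style distance/angle windows
(biotite's assigner), mapping helix/strand/other to {H, E, C}. Cα-only
assignment works on models lacking full backbones (and on the single-atom
pseudo-residues of the pocket fixtures); residues without Cα, non-standard
residues and chains shorter than the 5-residue window are labelled C. The
labels are invariant under rigid motion by construction.

## Terminal-disorder trimming

"Unmodeled" cannot be recovered from a model file alone (it is defined by
missing template support during modeling), so it is operationalized as a
maximal run of residues with score ≥ 0.6 (configurable) or an explicit
caller mask. Each candidate region is tested against five criteria with the
boundary semantics exactly as printed: length ≥ 10 passes; any intersecting
maximal helix/strand element of length > 5 fails (strictest reading — the
element need only intersect the region); median relative SASA must be
> 0.40 strictly; median contacts < 4 strictly; only N-/C-terminal regions
qualify. Medians are *lower medians* for even counts so boundary fixtures
are exact. Removal deletes the region's residues, preserving the numbering
of the rest; deleting an entire chain is refused and reported. Single pass
per terminus is the default; `iterate` mode repeats until quiescent, for the
case where an internal run becomes terminal after a tail is removed —
whether to iterate is genuinely open, so it is opt-in.

## Binding sites and degree of buriedness

Sites are defined by ligand proximity (any residue heavy atom within 4.5 Å
of any ligand heavy atom) or given explicitly. The degree of buriedness is a
LIGSITE-family grid scan: a 1.0 Å grid spans the site plus an 8 Å margin;
solvent points (outside every van der Waals sphere) within the margin are
scanned along 7 directions (3 axes, 4 cube diagonals) to a range of 10 Å
each way; a direction counts when protein blocks *both* sides
(protein–solvent–protein enclosure), computed by analytic ray–sphere
intersection. A point's DOB is 0–7; the site's DOB is the mean over pocket
points (DOB ≥ 1), 0 when no point shows enclosure. Adding atoms can only
raise a point's DOB.

Categorization: mean DOB ≥ 4.0 → `buried`; otherwise the template assembly
decides. Mapping the site through the model↔template alignment, if any atom
of a *non-aligned* template chain lies within 5.0 Å of a mapped site
residue, the template's stoichiometry documents a complementary surface that
the model lacks → `surface_noncomplete`; else `surface`. All DOB parameters
(spacing, margin, scan range, buried cutoff) are documented defaults of this
in-repo approximation, not literature constants — published analyses of this
kind do not disclose their parameterization, and the published
buried/surface fractions are not reproduction targets here. The source
prose and its figure legend disagree about which surface subcategory carries
the template-evidence qualifier; the prose reading is the default and a
`swap_noncomplete` flag inverts it.

## Quality harmonization and banding

`1 − TopScore`, `pLDDT/100`, QMEAN6 clamped to [0, 1]: all three land on a
0–1 higher-is-better scale, monotone in their native scores. TopScore bands
are half-open: high < 0.2 ≤ good < 0.4 ≤ low, with a cumulative mode where
"good" includes high (nested counting). The residue-score analyses —
grouping by secondary structure, binning by distance from the binding site
(minimum heavy-atom distance, 2 Å bins; both metric and width are pinned
choices, a Cα option exists), and binning models by template identity
(decade bins over 30–100%) — are exact partitions: no residue or model is
lost or duplicated.

## Treemap and metadata export

Treemap nodes span the four EC levels. A node's *size* counts representative
attachments under its prefix (a multi-EC representative counts once per leaf
it represents); its *color* is the mean harmonized score over scored
representatives, so unscored representatives occupy area with neutral color —
coverage and quality stay separate. Size is conserved (parent = Σ children)
and parent colors are the scored-count-weighted means of child colors.
Colors average over representatives only (they are the entities the map
displays), not over cluster members. The metadata CSV has a fixed column
order, deterministic row order (EC, then accession), RFC-4180 quoting, and
round-trips losslessly. The HTML treemap is a dependency-free inline-SVG
document (slice-and-dice layout, alternating split direction per level) with
the node table embedded as JSON.

## Synthetic generators

*Sequence families* mutate a random ancestor per member: each site flips
with probability 1 − target_identity to a uniformly drawn *different*
residue (no substitution matrix — identity, not phylogeny, is what the
consumers measure), resampling until the realized ancestor identity is
within ±0.05 of the target. Because members are equal-length, alignment
identity equals per-site identity. Two independent descendants at identity
t are related at about t² + (1−t)²/19 to each other — at the default family
identity 0.85 this keeps every member far above the 0.30 clustering cutoff,
and unrelated families align near the random-background identity (~0.1–0.2),
so the cutoff separates families cleanly.

*Structures* are built by natural-extension-reference-frame placement from
ideal bond geometry (N–Cα 1.458, Cα–C 1.525, C–N 1.329 Å; angles
111.2°/116.2°/121.7°; ω = 180°) with per-segment torsions: helix
φ=−57°/ψ=−47°, strand φ=−120°/ψ=+120°, coil torsions drawn per residue from
a broad sterically plausible range (φ ∈ [−160°, −50°], ψ uniform), which
almost never sustains a helix or strand window for more than a few
consecutive residues. Backbones that self-clash below 1.5 Å regenerate their
coil torsions up to a retry limit. Carbonyl O and an ideal tetrahedral Cβ
are added; side chains are not modeled.

*Pockets* are atom-lattice geometries (1.4 Å spacing, overlapping carbon
spheres, one pseudo-residue per atom): `enclosed` carves a cavity in a solid
block (the flat outer faces produce no spurious surface enclosure, so the
cavity dominates the mean DOB); `cleft` carves a hemispherical notch into a
slab; `flat` rests the ligand on an intact face. A template-assembly variant
adds a hovering second chain above the site for the noncomplete pathway.

*The study set* (`make_study_set`) bundles the default conditions used by
the end-to-end tests and the acceptance script: five families (sizes 8, 6,
5, 4, 2; lengths 120–160; ancestor identity 0.85) labelled `3.6.5.2`,
`1.1.1.1`, `2.3.1.12`, `3.4.21.1`, `6.3.2.1`, one bifunctional member
(`3.6.5.2;3.6.1.1`), a 42-residue model with a 12-residue high-score coil
tail (scores 0.7–0.9) on a confident helix body (0.1), and per-representative
raw scores and template identities. These sizes keep the full pipeline
(quadratic-ish alignment work, 960-point SASA, 1 Å DOB grids) comfortably
within interactive runtimes while still exercising every stage.

What the generators do *not* emulate: real substitution processes, indels,
domain architecture, side-chain packing, crystallographic artifacts, or the
actual error modes of structure predictors. Passing tests demonstrate that
the algorithms implement their stated conventions exactly and behave
correctly on controlled geometry — not that the default thresholds are
optimal for any particular real model collection.

## Degenerate inputs and tie-breaks (summary)

Empty sequence → alignment error; empty record set → empty tree but
clustering requires ≥ 1 record; equal-identity representative candidates →
longer sequence, then smallest accession; equal-length clustering order →
accession; even-sized medians → lower median; residues without Cα → coil,
excluded from contacts; unknown elements → carbon radius with warning;
whole-chain trims → refused; empty treemap → HTML export refused.

## Known limitations

Greedy representative-only clustering is order-dependent by design and not
equivalent to cascaded profile clustering at low identities near the cutoff.
The disorder threshold conflates "low confidence" with "unmodeled". The DOB
scan is grid- and direction-discretized; its mean is sensitive to the pocket
margin on open geometries. Harmonized scores from different sources share a
scale but not a calibration — a 0.7 from pLDDT and a 0.7 from QMEAN6 are not
the same statement about the model.
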