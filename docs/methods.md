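# Methods

## Scope and data model

The pipeline starts from *contact records*: one row per (structure,
chain, residue, atom, ligand instance) with a list of raw contact-type
labels, as produced by atomic-contact classifiers of the Arpeggio family.
It does not compute contacts from coordinates, cluster with external
tools, or assign secondary structure itself — those tools' *output
formats* are its inputs. Structure residues are lifted to UniProt
coordinates through SIFTS-style residue maps (the range dialect of
`pdb_chain_uniprot.tsv`, expanded per residue, or a per-residue TSV that
supports insertion codes such as `100A`). Residues mapping to more than
one accession (chimeric chains) are dropped as ambiguous and counted.

Two registry tables drive the evolutionary statistics and are data, not
logic:

- **Amino acids** — 20 canonical residues split 10/10 into an *early* era
  (Ala, Asp, Glu, Gly, Ile, Leu, Pro, Ser, Thr, Val) and a *late* era.
  Chronology ranks order report rows only; the default table follows the
  consensus order-of-addition within each era, with all early residues
  ranked before all late ones. No statistic depends on ranks.
- **Coenzyme classes** — 28 classes (27 database-derived plus ATP), each
  with a temporality (Ancient / LUCA / Post-LUCA / Unclassified), a
  nucleotide-derived flag (implies Ancient), a phosphate-containing flag,
  and member ligand codes (PDB chemical-component identifiers, unique
  across classes — duplicates are a hard error). MIO and Orthoquinone are
  stored but flagged excluded, leaving 26 analyzed classes. The
  Unclassified set is exactly {Thiamine diphosphate, Coenzyme M,
  Factor F430, Glutathione}. Temporalities not fixed by published
  statements follow the field's usual attributions and can be edited in
  `data/registry.yaml`, which round-trips bit-identically.

## Site calling

For each (accession, coenzyme class), `n_structures` is the number of
distinct structures in which the class is bound. A residue's interaction
ratio is `Fraction(n_present, n_structures)`; comparison against the
calling threshold (default 1/2) is exact rational arithmetic, so ties are
well-defined. Two published wordings disagree on the tie ("at least 50%"
vs "more than 50%"); the `ratio_inclusive` flag selects the reading and
defaults to inclusive.

Per-residue aggregation is over all structures of the protein: atom names
are unioned before the backbone / side-chain / both classification
(backbone = {N, C, CA, O}); grouped interaction types are unioned with
clashes removed. Records whose labels reduce to clashes alone are dropped
before presence counting, so a clash can never create a consensus
residue. Glycine, having no side-chain heavy atom, can only ever be
backbone-only; the generator enforces this and the tests assert it.

Raw label grouping is total on the known vocabulary and maps each label to
exactly one of nine groups (covalent, electrostatic, amide, vdw,
hydrophobic, aromatic, atom-pi, metal, clashes). Unknown labels are
warn-and-skip by default (`reject` available).

**Metal association.** The contact schema carries an optional
`environment` field: a metal-ion partner names the coenzyme instance whose
bound-molecule environment it shares. A site's metal tally counts ion
copies as distinct (structure, ion instance, element) observations;
mediation statistics use set semantics (a site either has ≥ 1 metal or
not; per-element fractions count a site once per element). The published
analyses do not state a spatial association rule; this environment-based
rule is ours and is documented here.

## Statistics

- **Composition**: counting unit is the site residue (once per site, not
  per structure or contact). Percentages per temporality or class;
  background from the full (representative) sequence set, non-canonical
  letters excluded and counted.
- **Chi-squared**: Pearson Σ(O−E)²/E, no continuity correction; expected
  from margins (contingency, df = (r−1)(k−1)) or supplied (goodness of
  fit, df = k−1); p-values from the χ² survival function, reported raw
  with no multiple-testing correction. Expected count 0 is an error;
  expected < 5 sets a warning flag. Both the temporality × era contingency
  test and the per-temporality goodness-of-fit against background are
  computed, since either reading of the published test is plausible.
- **Fractional difference**: FDᵢ = pᵢ(A) − pᵢ(B) in percentage points of
  per-amino-acid relative frequency, plus mean FD over the early and late
  sets. The source never prints the formula; published magnitudes (≈ 4.4,
  −11) are consistent with percentage points, and this interpretation is
  flagged as such. FD is antisymmetric and sums to zero by construction.
- **Background normalization**: era share divided by its background
  share, rescaled to sum to 100 (enrichment-ratio reading of a briefly
  described normalization; a raw mode is available by simply not
  normalizing). Background equal to composition maps to 50/50.
- **Type distribution**: default counting is residue × grouped-type (a
  residue contributes once to each group it exhibits); a `dominant` mode
  assigns one group per residue by fixed precedence (covalent > metal >
  electrostatic > aromatic > atom-pi > amide > hydrophobic > vdw), since
  the published figure does not state its counting unit.
- **Secondary structure**: codes collapsed to {h, b, c} (DSSP-style
  letters mapped helix→h, strand/bridge→b, rest→c). Redundancy removal is
  per residue: the *set* of codes across a protein's structures; content
  is counted over (residue, code) pairs. The dataset-wide background
  covers all mapped residues of dataset proteins (not all residues of the
  source database — the published baseline is ambiguous on this).
- **Fold diversity**: a site contributes an ECOD X-group when ≥ 1 of its
  residues lies in a domain of that group in any structure; counts are
  distinct X-groups per class, invariant to duplicated structures.
- **Exclusive sites**: ≥ 2 residues, all of one era. Conservation
  summaries report the fraction of covered residues with grade ≥ 7 and the
  fraction equal to the alignment's most frequent residue (MAX AA), with
  uncovered residues excluded and counted.

## Redundancy clustering

Greedy, longest-first (ties by accession), CD-HIT-style: a sequence joins
the first representative with identity ≥ threshold (default 0.90), else
founds a cluster, so representatives are always the longest members and
the procedure is deterministic. Identity is approximated as the maximum
number of exact positional matches over all ungapped offsets, divided by
the shorter length — exact for equal-length substitution variants; the
required property is agreement with a brute-force all-pairs oracle, not
bit-compatibility with the external tool. An exactly-conservative 5-mer
prefilter (at identity ≥ t, at least ⌈t·L⌉ − 4 − 5(L − ⌈t·L⌉) of the
candidate's 5-mers must occur in the representative) skips hopeless pairs
without changing any result. Sequences shorter than 10 residues are kept
as singletons with a warning. Note that under the shorter-length
denominator an exact substring has identity 1.0; the parallel lower
threshold reported alongside the main analysis (30%) is available via
config.

## Synthetic data

The generator emulates the statistical shape of a database survey, not its
geometry: per temporality, `n_proteins` proteins (default 200; 50 for
Unclassified), each with 1–3 structures (uniform), one planted site of
Poisson-distributed size (mean 8, min 2) in a 160-residue sequence, site
residues drawn early-vs-late by the planted occupancy and uniformly within
era, contact modes by the planted mode mix (glycine only in backbone-only
slots, preserving both the era and mode marginals), exactly one grouped
interaction type per site residue from the planted mix, per-structure
retention of each site contact (default 0.9 — this is what makes
interaction ratios non-trivial), clash-only extra records at rate 0.02,
author-numbering offsets of 0 or +100 to exercise SIFTS lifting,
per-protein ECOD domains, and a simple conservation model (site residues
high-grade with probability 0.6; MAX-AA identity 0.75).

Defaults echo the study conditions the pipeline is meant to emulate:
early occupancies 0.61 / 0.53 / 0.47 (Ancient / LUCA / Post-LUCA; 0.50
Unclassified), background 0.67 early, backbone-only fractions 0.24 / 0.13 /
0.10 / 0.15, metal-mediation rates 0.24 / 0.13 / 0.11 / 0.23 with an
element mix led by Mg²⁺ (0.55) then Ca²⁺, Mn²⁺, Fe²⁺, Zn²⁺, loop-rich
Ancient vs helix-rich Post-LUCA secondary structure. All are config, not
constants.

Two sampling-law choices matter for interpretation. Per-residue
quantities (era, mode, type) are i.i.d. draws, so their estimates carry
binomial/multinomial noise at the planted n. Metal mediation is planted by
**exact count** (stratified assignment of ⌈rate·n⌉ sites): it is a
site-level parameter with the smallest n, and stratifying makes the
realized rate equal the nominal one, so any estimator error is
attributable to the pipeline rather than to the generator's own draw.

What the synthetic data does **not** emulate: 3D geometry and distance
cutoffs, correlated residue composition (no phylogenetic structure — the
conservation table is a toy), multi-chain or multi-copy ligand
complexity beyond one coenzyme instance per structure, non-standard
residues at sites, and database deposition bias. Passing recovery tests
therefore shows the estimators are correct under the planted model, not
that real databases satisfy that model.

## Problem sizes used in the checks

The recovery checks run at 200 sites per temporality (mean site size 8;
~1,600 site residues per temporality) for occupancy, and 250 sites per
temporality (~2,000 residues) for mode/type/metal recovery, with ±3
percentage-point tolerances; ordering of the three occupancies is checked
over 100 seeded runs. Oracle-equivalence checks use 200 random small
datasets (≤ 10 proteins, ≤ 5 structures, ≤ 20 residues) for site calling
and 1,000 random 2×2 / 2×3 tables for the χ² statistic (agreement to
1e-10). End-to-end determinism is asserted byte-for-byte on full runs.

## Degenerate inputs and numerical conventions

Empty presence vectors, empty residue maps, all-unmappable contact sets,
sequences with no canonical residues, zero expected counts, grades outside
1–9, and empty conservation coverage are hard errors. Zero qualifying
sites, empty composition groups, and classes without ECOD coverage are
warnings with well-defined (empty) outputs. Ratios and clustering
thresholds compare as exact rationals (`Fraction`, thresholds via
`limit_denominator(10⁶)`); residue-name conflicts at one position resolve
by majority, ties lexicographic; all outputs are sorted deterministically
and floats written with a fixed format, so identical configs and seeds
give identical bytes.

## Known limitations

- The registry's class→ligand-code table is a curated, editable snapshot;
  the optional `fetch` command can pull the live cofactor list but its
  output still needs manual curation, and nothing else depends on it.
- The ungapped identity approximation understates identity for sequences
  whose alignment requires gaps; at the default 0.9 threshold on
  structure-database sequence sets this mainly affects borderline pairs.
- Temporality labels carry genuine scientific ambiguity (e.g. thiamine
  diphosphate's nucleotide nature argues for Ancient; glutathione behaves
  Ancient-like on several properties); they are deliberately data.
- Headline percentages from full-database snapshots are not reproducible
  from synthetic data; the pipeline reproduces *properties* (trends,
  estimator correctness, exact accounting), which is what the tests and
  the acceptance script verify.
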