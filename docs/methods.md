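# Methods

This note documents the models, conventions and deliberate simplifications
behind `glycopull`, in the spirit of a methods section: what is computed,
under which assumptions, and what the synthetic benchmarks do and do not
demonstrate.

## Glycan compositions and mass arithmetic

A glycan is represented as a *composition* — counts of Hex, HexNAc,
dHex (fucose) and NeuAc — plus an attachment class (N-linked, O-linked,
unspecified). Compositions carry no topology: two structurally different
glycans with the same counts are indistinguishable here, which is exactly
the level of information a precursor-mass search operates on.

Residue monoisotopic masses (Da): Hex 162.052824, HexNAc 203.079373,
dHex 146.057909, NeuAc 291.095417. These are the standard residue masses
(free monosaccharide minus water), so the delta mass of a composition is
the plain sum Σ count·mass with no further water correction. Displayed
masses are rounded half-even to 3 decimals; all five default-panel deltas
(2059.735, 2350.830, 1167.418, 1458.513, 1969.703 Da) and both PTM deltas
(+57.021 carbamidomethyl-Cys, +15.995 Met-ox) reproduce at that precision.

**sLe compatibility** is a composition-level *necessary* condition only:
a sialylated Lewis terminus (NeuAc–Hex–(Fuc)HexNAc) requires at least one
residue of each of the four classes. Sufficiency cannot be decided without
topology, and the returned reason strings say so explicitly. The rule is
monotone: adding residues never revokes compatibility.

**N-glycan classes** come from a documented, replaceable heuristic over
counts: oligomannose (HexNAc = 2, Hex ≥ 4, no dHex/NeuAc), paucimannose
(HexNAc ≤ 2, Hex ≤ 3), complex (HexNAc ≥ 4), hybrid (HexNAc = 3, Hex ≥ 4),
otherwise `other`. Real classification requires structure; this heuristic
exists so composition panels can be summarized consistently.

## Digestion and peptide masses

Chymotrypsin is modeled with the high-specificity rule — cleavage
C-terminal to F, W, Y, L, suppressed before proline; the low-specificity
M/H sites are excluded by default but the cleavage-residue set is a
parameter. Up to two missed cleavages are enumerated by default, with a
5–60 residue peptide window as a practical search-space bound; all three
are configurable. Coordinates are 0-based half-open everywhere.

Peptide masses use the standard amino-acid monoisotopic residue table
(via pyteomics) plus water 18.010565 Da; proton mass 1.007276 Da for m/z
conversion. Cysteines are assumed fully carbamidomethylated (fixed
modification, +57.02146 Da); methionine oxidation (+15.99491 Da) is
enumerated as a variable modification per peptide. One glycan per
peptide: the search treats a glycopeptide as peptide + one composition
delta, with the attachment constraint that N-linked glycans require an
Asn and O-linked a Ser/Thr in the sequence. Multi-glycosylated peptides
and site localization within the peptide are out of scope.

## Spectrum matching and validation

The matcher is a deliberately transparent stand-in for a commercial
search engine. Candidates (peptide × panel glycan × Met-ox state) are
sorted by theoretical neutral mass; a spectrum's neutral precursor mass
(from PEPMASS and CHARGE; charge-missing spectra assume 2+ with a logged
warning) is looked up by binary search at 10 ppm tolerance. Matches are
ordered by |ppm error|, then matched-backbone-ion count (descending),
then accession — a fixed tie-break for determinism — and by default one
best match per spectrum is retained.

Backbone scoring counts theoretical singly charged b/y ions of the
peptide (glycan treated as entirely lost, the dominant behavior in HCD)
with a peak within 0.02 Da; intensity plays no role. A match is
**high confidence** when ≥ 6 backbone ions are matched (inclusive
threshold, configurable) and the precursor is within tolerance;
otherwise **low**. The threshold is a package default chosen to separate
full planted fragment series (≥ 8 ions for a 5-mer) from the sparse
constructed decoys (≤ 2 matched ions by construction); it is not an FDR
statement, and no target-decoy FDR estimation is attempted.

**Oxonium validation**: a spectrum passes the sLe filter iff each of the
three marker classes has ≥ 1 detected peak within the product tolerance —
HexNAc class {204.0867, 186.0761, 168.0655, 138.0550, 126.0550}, NeuAc
class {292.1027, 274.0921}, HexNAc-Hex disaccharide {366.1395} (singly
protonated). Detection uses a relative intensity floor (default 1 % of
the base peak) so the decision is invariant to uniform intensity
scaling. Class-level detection (any member ion) is used rather than
requiring specific ions.

## Curation

A run manifest labels each MS run as `eselectin_pulldown`, `igg_control`
or `no_calcium_control`. Evidence is aggregated per protein accession
(protein inference across shared peptides is out of scope; the match's
accession is taken as given). "Detected in a run" means ≥ 1 glycopeptide
match from a spectrum of that run — presence/absence, no intensity
threshold. The final-list logic is:

1. **differential filter** — keep proteins observed in ≥ 1 pulldown run
   and zero control runs (exclusivity at the protein level); proteins
   seen only in controls are dropped silently (debug-logged), being the
   expected background;
2. **confidence rule** — keep high-confidence proteins, or
   low-confidence proteins with ≥ 1 oxonium-validated match (the
   oxonium filter standing in for manual spectrum validation);
3. **linkage partition** — count proteins with O-linked evidence,
   N-linked evidence, both, and the union; inclusion–exclusion
   (union = O + N − both) holds identically because every curated
   protein carries at least one typed glycan match.

Each stage only removes entries, so final ⊆ differential ⊆ evidence.

## Target Score

The score is an additive, weight-parameterized prioritization over an
annotation table with a fixed organ vocabulary (brain, heart, lung,
liver, kidney, pancreas, colon):

    total = w_c·cancer_association + w_p·n_unfavorable_prognosis
          + w_m·[membrane_localized] − w_h·Σ_vital organs level

with expression levels encoded not_detected = 0 < low = 1 < medium = 2 <
high = 3 and all weights defaulting to 1. The published family of
prioritization scores varies between ordinal sums, indicator variables
and normalized terms; this parameterization covers those variants by
choice of weights and by how the data preparer encodes the ordinals
(e.g., capping an ordinal at 1 yields an indicator). The vital-organ
list approximates "relevant healthy organs for off-target risk" and is
configurable. Ranking is by descending total, ties broken by lower
healthy penalty (prefer the safer target), then accession; ranks are a
permutation of 1..n and independent of input order. The score is
monotone in each reward field, antitone in each penalized expression
level, and scale-equivariant in the weights.

## Synthetic data

The generator produces the complete input bundle — proteome FASTA,
per-run MGF, run manifest, glycan panel, annotation table — from a
single seeded NumPy generator stream; identical seeds give
byte-identical files, and the seed is recorded in the FASTA headers and
the ground-truth JSON.

*Proteome*: by default 40 proteins of 80–200 uniformly drawn residues,
each resampled until it contains ≥ 1 chymotryptic site, ≥ 1 Asn and
≥ 1 Ser/Thr, so both linkage types are plantable. *Run layout*: two
pulldown replicates plus one IgG and one no-Ca²⁺ control. *Spectra*: 20
true glycopeptides planted in pulldown runs and 10 decoys by default,
plus up to 6 contaminant proteins planted in control runs, half of which
also bleed into a pulldown run so the differential subtraction is
actually exercised (a protein seen in any control must be removed even
when present in pulldowns).

True and contaminant spectra carry the precursor at the exact
glycopeptide m/z (charge 2–3), the full singly charged b/y series, one
marker ion from each oxonium class, and a base peak at the glycan-loss
[peptide+H]⁺ ion. Intensities are fixed documented constants: base peak
1.0, backbone 0.1–0.5, oxonium 0.2–0.8, noise ≤ 0.05. The `noise`
parameter (0–1) scales both the number of uniform random peaks (up to
40) and a precursor jitter bounded by half the search tolerance
(≤ 5 ppm), so planted precursors always remain matchable.

Decoys are *constructed*, not sampled from targets, so ground-truth
labels are unambiguous: off-mass decoys sit 25 ppm from their candidate
(outside tolerance) and additionally lack an oxonium class; unvalidated
decoys are on-mass for a dedicated decoy-pool protein but carry a
backbone budgeted to ≤ 2 matched theoretical ions and a missing oxonium
class, so they can only yield a low-confidence, non-validated match that
the curation rules must discard. Planted peptides are 7–25 residues long
(making chance sequence collisions, including Leu/Ile isobars,
negligible) and every planted (peptide, glycan) pair is certified
*mass-unambiguous*: the generator builds the full candidate index and
redraws until no other protein owns a candidate within the widest
reachable precursor window (16 ppm for on-mass spectra, 41 ppm for
offset decoys). This is a property of the benchmark design, not of the
pipeline: it guarantees that ground-truth labels stay exact at every
noise level, so benchmark failures indicate pipeline defects rather than
constructed ambiguities.

The target/decoy/background protein pools are disjoint (50 % / 25 % /
25 % of the proteome). The annotation generator gives the planted top
target maximal reward fields (cancer 3, prognosis 8, membrane yes) and
zero healthy expression (total 12 at unit weights) while bounding every
other protein's total at 6, so rank 1 is guaranteed by construction.

**What passing these benchmarks shows — and does not.** Noise-free runs
recover exactly the planted protein set (precision = recall = 1), no
contaminant ever reaches the final list, and the Venn counts equal the
planted design; this validates the curation logic, the matching
arithmetic and the bookkeeping. It does not demonstrate performance on
real data: the generator has uniform residue composition (real proteomes
do not), no isotope envelopes, no co-isolation chimeras, no
retention-time structure, no shared peptides between proteins, single
glycans per peptide, and decoys far easier than real near-isobaric false
candidates. Scores and thresholds validated here should be re-examined
against annotated real spectra before production use.

## Numerical and I/O conventions

* ppm error is signed, relative to the theoretical mass:
  1e6·(obs − theo)/theo; tolerance checks are inclusive (≤).
* Binary search over the sorted candidate-mass array brackets the window
  conservatively, then each candidate is re-checked with the exact ppm
  formula, so results equal a linear scan by construction.
* MGF I/O goes through pyteomics, with a structural pre-pass that
  rejects unterminated BEGIN IONS blocks (addressed by block index);
  spectrum identifiers come from TITLE; peak lists are sorted on read.
* All tabular outputs are TSV with fixed column orders; JSON outputs are
  key-sorted; result files are written atomically (temp file + rename);
  reruns of an identical config are byte-identical, and the run log
  records version, config hash (destination-independent), seed and the
  Venn counts.
* Degenerate inputs fail loudly and early: empty proteome or glycan
  panel, all-zero compositions, orphan spectra (unmapped run), duplicate
  accessions in ranking, and missing vital organs in an annotation are
  all errors naming the offending record.

## Problem sizes

Default benchmark sizes — 40 proteins (~10⁴ candidate glycopeptides at
default settings), 30–40 spectra per experiment, 10 independent seeds
per aggregate statement — were chosen so the entire acceptance
computation reruns in seconds while still exercising every code path
(multi-run evidence, both linkage types, all decoy kinds, contaminant
bleed-through). All sizes are parameters of the generator and scale up
without code changes.

## Known limitations

* No FDR control; confidence tiers are transparent ion-count rules.
* No protein inference/parsimony; shared peptides inflate per-accession
  evidence.
* Composition-level glycan handling only; no structure, linkage or
  site-localization claims.
* Chymotrypsin specificity is a fixed rule; real enzymes show
  context-dependent cleavage kinetics.
* The Target Score is a parameterization of an additive prioritization
  family; absolute totals are not comparable across weight choices, only
  rankings under a fixed configuration.
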