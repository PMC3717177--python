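# Methods

## The migration problem

Two repository data models for MS/MS identification data are bridged. The
*source* shape is study-centric: a study is a set of samples; each sample
carries free-text metadata (tissue, cell type, disease state, study
design, summary, protocol), taxon labels, references to MGF peak-list
files, and flat peptide identifications in which each peptide-spectrum
match (PSM) lists its peptide→protein assertions explicitly, one per
(protein accession, search engine) pair. The *target* shape is
experiment-centric: a project is a set of experiments; identifications
are nested, protein items containing the peptide items that support
them. Neither model supports protein grouping or parsimony inference, so
none is attempted: conversion is a faithful structural re-arrangement.

Four rules govern conversion:

1. one study → one project, one sample → one experiment (a per-sample
   split flag exists but defaults off, keeping the mapping 1:1);
2. a peptide asserted against *k* proteins yields exactly *k*
   content-identical peptide items, one under each protein item;
3. a protein reported redundantly by *n* engines appears *n* times, each
   instance tagged with its engine and holding that engine's peptide
   set — no merging, no rescoring;
4. modification accessions are re-labelled from the Unimod-style to the
   PSI-MOD-style vocabulary with mass deltas untouched; unmapped
   accessions are carried through verbatim and listed in the conversion
   report; free-text metadata is copied byte-for-byte.

Because rule 2 duplicates peptide items *by design*, raw item counts are
not conserved. Migration consistency is therefore defined over three
quantities that must survive conversion exactly: total spectra, distinct
peptide species per sample (spectrum reference + sequence + the multiset
of (position, mass delta) sites, deltas rounded to 1e-4 Da so the key is
invariant under re-labelling and re-serialisation), and distinct
(protein accession, engine) identifications per sample. The summary
statistics (projects, experiments, distinct taxa, proteins,
modification sites, peptides, spectra) count proteins and peptides by the
same definitions.

## The delta-m/z validator

For each PSM with annotated charge z ≥ 1:

    M        = Σ residue_mass(aa) + m(H2O) + Σ site deltas
    m/z_theo = (M + z·m_proton)/z
    Δ        = m/z_observed − m/z_theo        [Th]

All masses are monoisotopic (residue table frozen to ≥6 decimals;
m(H2O) = 18.010565 Da, m_proton = 1.007276 Da); isoleucine and leucine
share one mass. The theoretical mass includes *every* annotated site,
reported or fixed — a spurious fixed annotation therefore shifts Δ, which
is exactly what makes it detectable. A PSM with charge 0 has no
theoretical m/z; it is emitted without a delta and routed to the
zero-charge detector.

### Detector definitions and thresholds

Scopes are samples. Thresholds (all configurable via `QcConfig`):

| parameter | default | role |
|---|---|---|
| `tol` | 0.01 Th | half-width for matching Δ against a modification signature |
| `outlier_tol` | 0.1 Th | \|Δ\| above which a PSM is an outlier |
| `charge_match_tol` | 0.05 Th | window for an alternative charge to explain an outlier |
| `max_charge` | 8 | upper bound of the z′ scan and of charge inference |
| `min_frac` | 0.05 | signature-matching fraction required for class i |
| `severity_threshold` | 0.5 | above it, a correction (not an annotation) is suggested |

`tol` and `outlier_tol` work because the signatures in play (15.9949/z,
label deltas of ~227/z Th) are separated by far more than 0.01 Th on any
instrument this data plausibly comes from. `charge_match_tol` is wider
than `tol` deliberately: alternative charges displace Δ by hundreds of
Th, so widening the window to 0.05 Th costs no specificity while keeping
the z′ decision robust to realistic precursor noise (at 0.005 Th
Gaussian noise, 0.01 Th would reject ~5% of correct charges; 0.05 Th
rejects essentially none).

* **Class i (no modifications reported).** A scope with *zero*
  modification sites, where at least `min_frac` of PSMs have Δ matching
  some single-modification signature d/z within `tol`, is flagged; the
  affected set is every PSM with |Δ| > `tol`. Requiring corroborating
  delta evidence keeps genuinely unmodified datasets clean.
* **Class ii (missing Met-ox).** Only in scopes that *do* report
  modifications (that distinction is what separates ii from i): a PSM
  with an unoxidised methionine available (fewer oxidation sites than
  Met residues) and |Δ − 15.994915/z| < `tol`.
* **Class iii (double label).** Structural test first: two modifications
  of the same label family at one position (light + heavy). Fallback
  delta test: a label-bearing PSM with Δ ≈ −Δ_light/z. The structural
  route needs no mass arithmetic and works at any charge.
* **Class iv (zero charge).** Annotated charge 0; no delta computable.
* **Class v (wrong charge).** |Δ| > `outlier_tol`, and an exhaustive scan
  of z′ ∈ 1..`max_charge`, z′ ≠ z, finds |Δ(z′)| < `charge_match_tol`.
  A PSM whose outlier is already explained by a class-i/ii signature is
  excluded; a PSM with a structural label conflict is *not* excluded —
  its scan instead subtracts the spurious fixed-label mass (the mass the
  corrector will restore), so co-occurring label and charge defects are
  both found. Classes may otherwise co-occur freely, as they do in real
  migrated data.

Severity is the affected fraction of the scope's PSMs. The
`severity_threshold` gates only the *suggested_correction* field of a
report (below it, `annotate_only`); the correction functions themselves
apply to whatever findings they are handed — the caller, not the
detector, decides the correction policy.

## Corrections

Applied to the target shape, in the fixed order label removal → charge
inference → charge reassignment, each returning a modified deep copy and
an append-only log with exactly one entry per mutated (or deliberately
unmutated) site or PSM:

* **Label removal (iii):** at each conflicted position the site with
  origin `fixed_annotation` is dropped, the reported one kept. When both
  forms are `reported` there is no mechanical basis for choosing — the
  site is logged `annotate_only` and left alone.
* **Charge inference (iv):** z = round(M/(m/z_obs − m_proton)), ties
  rounding half away from zero (implemented explicitly for platform
  determinism), clamped to ≥ 1, rejected above `max_charge`. Failures
  are logged, never guessed. Spectra identified by no peptide keep
  charge 0: with no sequence there is no M.
* **Charge reassignment (v):** the suggested z′ is accepted only after
  recomputing |Δ(z′)| < `charge_match_tol` against the current
  (post-label-removal) annotations; otherwise `annotate_only`.

Classes i and ii are detect-and-annotate only: inserting modification
sites risks creating new errors, and placement is ambiguous whenever
several candidate residues exist. An opt-in helper (`--add-metox`) adds
a missing oxidation only when the peptide contains exactly one Met, and
logs it under a distinct `add_modification` action.

A PSM duplicated under several protein items is mutated in all copies
and logged once.

## The modification table

A flat, user-replaceable TSV maps Unimod-style accessions to
PSI-MOD-style accessions with name, elemental composition of the delta,
monoisotopic delta, residue specificity, and (for isotopic labelling
reagents) a family/role registry with heavy > light enforced. The
bundled table is a curated synthetic stand-in covering the common cases
(oxidation, carbamidomethyl, carbamyl, deamidation, phosphorylation,
acetylation, ICAT light/heavy, iTRAQ); the PSI-MOD accession strings are
plausible placeholders, and correctness rests on the per-entry elemental
composition, which the test suite verifies against an independent
elemental-mass oracle to 1e-4 Da. Unmapped accessions degrade
gracefully: carried through with their mass delta and reported, never
dropped.

## The synthetic generator

The generator emulates the statistical shape of a study-centric shotgun
submission, not its spectra: tryptic-like random peptides (7–20 residues,
C-terminal K/R), charges 2–3, oxidation on ~30% of methionines,
phosphorylation on ~10% of S/T/Y, a heavy isotopic label on ~20% of
cysteines, 1–2 search engines per sample reporting redundantly, ~20% of
peptides shared between two proteins, and the six free-text metadata
fields with unicode content. Precursor m/z is *computed* from the true
sequence, modifications and charge (optionally plus Gaussian noise), so
the validator closes exactly over clean output — that closure is the
generator/validator consistency check, not an empirical claim. Peak
lists are decoy fragments: nothing downstream inspects fragment ions,
and tests must not either. Same seed ⇒ byte-identical files.

Defect injection follows the class definitions (per-sample stripping for
class i; one oxidation annotation removed per affected PSM for class ii,
matching the "some values missing" phenomenon; fixed light labels added
at heavy-labelled positions for iii; zeroed and ±1-displaced charges for
iv/v, mutually exclusive per PSM) and records every injection in a
ground-truth table sufficient to score any detector or corrector.

What passing tests on this generator do **not** show: robustness to
calibration drift or systematic mass error, isotope-peak
mis-selection (±1.00335/z offsets, deliberately out of scope), engines
disagreeing on the same spectrum, real metadata vocabulary, or realistic
modification co-occurrence. The detectors' near-perfect confusion matrix
is a property of well-separated signatures under small noise — real data
adds overlap the thresholds must be re-examined against.

## Numerical and format choices

Monoisotopic arithmetic throughout (average masses would smear every
signature); floats serialised with `repr` in XML/MGF headers so
round-trips are exact; peaks written to 6 decimals; MGF charge 0 encoded
as an absent CHARGE line; unknown MGF headers preserved verbatim;
modification positions are 1-based with 0 = N-term and len+1 = C-term.
XML documents validate against bundled XSDs on read *and* write, with
offending element paths in the error. Parsing preserves document order
everywhere; detector and corrector iteration orders are deterministic.

Problem sizes in the test and acceptance runs (10×5×200 PSMs for the
nullity check, 600-PSM batches per defect class, 200 random datasets for
conservation) are the package's chosen verification scale; all
computations are linear in PSM count and run in seconds.

## Known limitations

- The charge scan bounds z′ at 8; exotic precursors beyond that are
  reported as errors rather than corrected.
- Class-v reassignment assumes exactly one alternative charge explains
  the outlier; coincidental second matches (rarer than 1 in 10⁴ in the
  generator's mass range) would be accepted silently.
- The both-forms-reported guard for label removal mechanises a policy
  for a situation whose real-world resolution is submitter contact; it
  is a plausible rule, not ground truth.
- No FDR modelling, no rescoring, no fragment-level checks — the toolkit
  audits annotations against precursors, nothing deeper.
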