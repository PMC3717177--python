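"""Delta-m/z validation, defect detection, count checks and summaries."""

import copy

import pytest

from idmigrate.convert import convert_study
from idmigrate.formats.model import (
    ModOrigin,
    ModificationSite,
    PeptideIdentification,
    ProteinIdentification,
    Sample,
    Spectrum,
    StudyDataset,
)
from idmigrate.masscalc import peptide_mass, theoretical_mz
from idmigrate.qc import (
    IssueClass,
    QcError,
    SummaryStats,
    cross_validate_counts,
    detect_issues,
    summarize,
    validate_delta_mz,
)

METOX = 15.994915


def _target_psm(pid, sequence, true_mods, true_charge, annotated_mods=None,
                annotated_charge=None):
    """One PSM whose spectrum reflects the *true* state while the annotation
    may disagree — the anatomy of every defect class."""
    mass = peptide_mass(sequence, [(p, d) for p, d in true_mods])
    mz = theoretical_mz(mass, true_charge)
    if annotated_mods is None:
        annotated_mods = [
            ModificationSite(p, "MOD:TEST", d, ModOrigin.REPORTED) for p, d in true_mods
        ]
    charge = true_charge if annotated_charge is None else annotated_charge
    psm = PeptideIdentification(
        peptide_id=pid, sequence=sequence, spectrum_ref=f"sp_{pid}",
        charge_claimed=charge, modifications=annotated_mods,
    )
    spectrum = Spectrum(f"sp_{pid}", f"sp_{pid}", mz, charge)
    return psm, spectrum


def _dataset(pairs):
    psms, spectra = zip(*pairs)
    sample = Sample(
        sample_id="s1",
        spectra=list(spectra),
        proteins=[ProteinIdentification("P1", "Mascot", peptides=list(psms))],
    )
    return StudyDataset(shape="target", study_id="T", samples=[sample])


def test_self_consistent_psm_has_zero_delta():
    ds = _dataset([_target_psm("a", "PEPTIDEK", [], 2)])
    (rec,) = validate_delta_mz(ds)
    assert rec.delta_mz == pytest.approx(0.0, abs=1e-9)


def test_stripped_metox_shifts_delta_by_half_an_oxygen():
    ds = _dataset(
        [_target_psm("a", "AMPTIDEK", [(2, METOX)], 2, annotated_mods=[])]
    )
    (rec,) = validate_delta_mz(ds)
    assert rec.delta_mz == pytest.approx(METOX / 2, abs=1e-6)


def test_zero_charge_psm_has_no_delta_and_routes_to_class_iv(ptm_table):
    ds = _dataset([_target_psm("a", "PEPTIDEK", [], 2, annotated_charge=0)])
    (rec,) = validate_delta_mz(ds)
    assert rec.delta_mz is None and rec.charge_used == 0
    reports = detect_issues([rec], ds, ptm_table)
    assert [r.issue_class for r in reports] == [IssueClass.IV_ZERO_CHARGE]
    assert reports[0].psm_refs == ["a"]
    assert reports[0].severity == 1.0


def test_unresolvable_spectrum_names_the_psm():
    ds = _dataset([_target_psm("a", "PEPTIDEK", [], 2)])
    ds.samples[0].spectra = []
    with pytest.raises(QcError, match="'a'"):
        validate_delta_mz(ds)


def test_wrong_charge_detected_with_correct_suggestion(ptm_table):
    # generated at z=3, annotated z=2 -> class v, suggested 3
    ds = _dataset([
        _target_psm("a", "PEPTIDEKPEPTIDEK", [], 3, annotated_charge=2),
        _target_psm("b", "AAGGAAK", [], 2),
    ])
    recs = validate_delta_mz(ds)
    reports = detect_issues(recs, ds, ptm_table)
    assert [r.issue_class for r in reports] == [IssueClass.V_WRONG_CHARGE]
    assert reports[0].details["suggested_charges"] == {"a": 3}


def test_double_label_detected_structurally(ptm_table):
    heavy = ptm_table.resolve("UNIMOD:106")
    light = ptm_table.resolve("UNIMOD:105")
    mods = [
        ModificationSite(3, heavy.unimod_acc, heavy.mono_delta, ModOrigin.REPORTED),
        ModificationSite(3, light.unimod_acc, light.mono_delta,
                         ModOrigin.FIXED_ANNOTATION),
    ]
    ds = _dataset([
        _target_psm("a", "AACAAK", [(3, heavy.mono_delta)], 2, annotated_mods=mods)
    ])
    recs = validate_delta_mz(ds)
    # the spurious fixed light label inflates the theoretical mass
    assert recs[0].delta_mz == pytest.approx(-light.mono_delta / 2, abs=1e-6)
    reports = detect_issues(recs, ds, ptm_table)
    assert [r.issue_class for r in reports] == [IssueClass.III_DOUBLE_LABEL]
    assert reports[0].details["conflicts"]["a"] == [(3, "UNIMOD:105", "UNIMOD:106")]


def test_no_mods_scope_needs_corroborating_deltas(ptm_table):
    # genuinely unmodified dataset: zero sites but zero deltas -> clean
    clean = _dataset([_target_psm(f"p{i}", "PEPTIDEK", [], 2) for i in range(10)])
    assert detect_issues(validate_delta_mz(clean), clean, ptm_table) == []
    # stripped dataset: zero sites, deltas match modification signatures
    stripped = _dataset(
        [_target_psm(f"p{i}", "AMPTIDEK", [(2, METOX)], 2, annotated_mods=[])
         for i in range(10)]
    )
    reports = detect_issues(validate_delta_mz(stripped), stripped, ptm_table)
    assert [r.issue_class for r in reports] == [IssueClass.I_NO_MODS]
    assert len(reports[0].psm_refs) == 10


def test_missing_metox_flagged_only_in_scopes_reporting_mods(ptm_table):
    phospho = ptm_table.resolve("UNIMOD:21")
    pairs = [
        _target_psm("ox", "AMPTIDEK", [(2, METOX)], 2, annotated_mods=[]),
        _target_psm("ph", "ASPTIDEK", [(2, phospho.mono_delta)], 2,
                    annotated_mods=[ModificationSite(2, phospho.unimod_acc,
                                                     phospho.mono_delta)]),
    ]
    ds = _dataset(pairs)
    reports = detect_issues(validate_delta_mz(ds), ds, ptm_table)
    assert [r.issue_class for r in reports] == [IssueClass.II_MISSING_METOX]
    assert reports[0].psm_refs == ["ox"]


def test_clean_generated_dataset_yields_no_reports(clean_batch, ptm_table):
    for ds in clean_batch.datasets:
        target, _ = convert_study(ds, ptm_table)
        recs = validate_delta_mz(target)
        assert all(abs(r.delta_mz) < 1e-6 for r in recs)
        assert detect_issues(recs, target, ptm_table) == []


# ---------------------------------------------------------------------------
# count cross-validation

def test_converted_pair_passes_and_mutations_fail(clean_batch, ptm_table):
    source = clean_batch.datasets[0]
    target, _ = convert_study(source, ptm_table)
    assert cross_validate_counts(source, target).passed

    mutated = copy.deepcopy(target)
    # delete one PSM everywhere it occurs
    victim = mutated.samples[0].proteins[0].peptides[0].peptide_id
    for sample in mutated.samples:
        for protein in sample.proteins:
            protein.peptides = [p for p in protein.peptides if p.peptide_id != victim]
    result = cross_validate_counts(source, mutated)
    assert not result.passed
    (failure,) = [c for c in result.failures() if c.name == "peptide_species"]
    assert failure.source_value - failure.target_value == 1


def test_expansion_duplicates_do_not_fail_the_check(ptm_table):
    """A peptide item duplicated under two proteins is by-design, not a loss."""
    psm, spectrum = _target_psm("a", "PEPTIDEK", [], 2)
    from idmigrate.formats.model import ProteinMapping

    src_psm = copy.deepcopy(psm)
    src_psm.protein_mappings = [ProteinMapping("P1", "E"), ProteinMapping("P2", "E")]
    source = StudyDataset(
        shape="source", study_id="T",
        samples=[Sample(sample_id="s1", spectra=[spectrum], peptides=[src_psm])],
    )
    target, _ = convert_study(source, ptm_table)
    assert sum(len(p.peptides) for p in target.samples[0].proteins) == 2
    assert cross_validate_counts(source, target).passed


# ---------------------------------------------------------------------------
# summary statistics

def test_summary_counts_match_generator_bookkeeping(clean_batch, ptm_table):
    targets = [convert_study(ds, ptm_table)[0] for ds in clean_batch.datasets]
    stats = summarize(targets)
    truth = clean_batch.ground_truth
    assert stats.n_projects == len(clean_batch.datasets)
    assert stats.n_experiments == sum(len(d.samples) for d in clean_batch.datasets)
    assert stats.n_peptides == len(truth.psms)
    assert stats.n_spectra == len(truth.psms)  # one spectrum per PSM
    assert stats.n_modification_sites == sum(
        len(t.true_mods) for t in truth.psms.values()
    )
    taxa = {t for d in clean_batch.datasets for s in d.samples for t in s.taxa}
    assert stats.n_distinct_taxa == len(taxa)


def test_empty_dataset_summarizes_to_zeros():
    stats = summarize(StudyDataset(shape="target", study_id="E"))
    assert stats == SummaryStats(1, 0, 0, 0, 0, 0, 0)


def test_shared_peptide_counts_once_but_both_proteins(ptm_table):
    psm, spectrum = _target_psm("a", "PEPTIDEK", [], 2)
    sample = Sample(
        sample_id="s1", spectra=[spectrum],
        proteins=[
            ProteinIdentification("P1", "E", peptides=[copy.deepcopy(psm)]),
            ProteinIdentification("P2", "E", peptides=[copy.deepcopy(psm)]),
        ],
    )
    stats = summarize(StudyDataset(shape="target", study_id="T", samples=[sample]))
    assert stats.n_peptides == 1 and stats.n_proteins == 2
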