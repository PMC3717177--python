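"""Corrections: label removal, charge inference, reassignment, audit."""

import pytest

from idmigrate.cli import _apply_corrections
from idmigrate.convert import convert_study
from idmigrate.correct import (
    fix_zero_charges,
    reassign_wrong_charges,
    remove_fixed_labels,
)
from idmigrate.formats.model import (
    ModOrigin,
    ModificationSite,
    ProteinIdentification,
    Sample,
    Spectrum,
    StudyDataset,
    iter_psms,
)
from idmigrate.masscalc import peptide_mass, theoretical_mz
from idmigrate.qc import (
    IssueClass,
    QcConfig,
    SuggestedCorrection,
    detect_issues,
    validate_delta_mz,
)
from idmigrate.synthgen import GeneratorConfig, generate

from test_qc import _dataset, _target_psm


def _double_label_dataset(ptm_table, light_origin=ModOrigin.FIXED_ANNOTATION):
    heavy = ptm_table.resolve("UNIMOD:106")
    light = ptm_table.resolve("UNIMOD:105")
    mods = [
        ModificationSite(3, heavy.unimod_acc, heavy.mono_delta, ModOrigin.REPORTED),
        ModificationSite(3, light.unimod_acc, light.mono_delta, light_origin),
    ]
    return _dataset(
        [_target_psm("a", "AACAAK", [(3, heavy.mono_delta)], 2, annotated_mods=mods)]
    )


def test_fixed_light_label_removed_and_delta_restored(ptm_table):
    ds = _double_label_dataset(ptm_table)
    corrected, log = remove_fixed_labels(ds, ptm_table=ptm_table)
    (rec,) = validate_delta_mz(corrected)
    assert rec.delta_mz == pytest.approx(0.0, abs=1e-9)
    (entry,) = log.entries
    assert entry.action == SuggestedCorrection.REMOVE_FIXED_LABEL
    # one reported heavy site survives
    (_, psm), = iter_psms(corrected)
    assert [m.origin for m in psm.modifications] == [ModOrigin.REPORTED]
    # input untouched
    (_, original), = iter_psms(ds)
    assert len(original.modifications) == 2


def test_both_reported_forms_left_alone_with_annotation(ptm_table):
    ds = _double_label_dataset(ptm_table, light_origin=ModOrigin.REPORTED)
    corrected, log = remove_fixed_labels(ds, ptm_table=ptm_table)
    (_, psm), = iter_psms(corrected)
    assert len(psm.modifications) == 2  # unchanged
    (entry,) = log.entries
    assert entry.action == SuggestedCorrection.ANNOTATE_ONLY


def test_clean_dataset_unchanged_with_empty_log(ptm_table):
    ds = _dataset([_target_psm("a", "PEPTIDEK", [], 2)])
    corrected, log = remove_fixed_labels(ds, ptm_table=ptm_table)
    assert log.entries == []
    (_, a), = iter_psms(ds)
    (_, b), = iter_psms(corrected)
    assert a == b


def test_zero_charge_inferred_from_mass_and_mz():
    ds = _dataset([_target_psm("a", "PEPTIDE", [], 2, annotated_charge=0)])
    # the example numbers: M = 799.359964 Da observed at 400.687258 Th
    assert ds.samples[0].spectra[0].precursor_mz == pytest.approx(400.687258, abs=1e-6)
    corrected, log = fix_zero_charges(ds)
    (_, psm), = iter_psms(corrected)
    assert psm.charge_claimed == 2
    assert corrected.samples[0].spectra[0].precursor_charge == 2
    (entry,) = log.entries
    assert (entry.before, entry.after) == (0, 2)


def test_unidentified_spectra_keep_charge_zero():
    ds = _dataset([_target_psm("a", "PEPTIDEK", [], 2)])
    ds.samples[0].spectra.append(Spectrum("orphan", "orphan", 500.0, 0))
    corrected, log = fix_zero_charges(ds)
    orphan = [s for s in corrected.samples[0].spectra if s.spectrum_id == "orphan"]
    assert orphan[0].precursor_charge == 0 and log.entries == []


def test_uninferable_charge_logged_never_guessed():
    psm, _ = _target_psm("a", "PEPTIDEK", [], 2, annotated_charge=0)
    spectrum = Spectrum("sp_a", "sp_a", 0.5, 0)  # below the proton mass
    sample = Sample(sample_id="s1", spectra=[spectrum],
                    proteins=[ProteinIdentification("P1", "E", peptides=[psm])])
    ds = StudyDataset(shape="target", study_id="T", samples=[sample])
    corrected, log = fix_zero_charges(ds)
    (_, out), = iter_psms(corrected)
    assert out.charge_claimed == 0
    (entry,) = log.entries
    assert entry.action == SuggestedCorrection.ANNOTATE_ONLY
    assert "not inferable" in entry.note


def test_wrong_charge_reassigned_only_when_it_fits(ptm_table):
    ds = _dataset([
        _target_psm("a", "PEPTIDEKPEPTIDEK", [], 3, annotated_charge=2),
        _target_psm("b", "AAGGAAK", [], 2),
    ])
    reports = detect_issues(validate_delta_mz(ds), ds, ptm_table)
    corrected, log = reassign_wrong_charges(ds, reports)
    by_id = {p.peptide_id: p for _, p in iter_psms(corrected)}
    assert by_id["a"].charge_claimed == 3
    assert by_id["b"].charge_claimed == 2
    (entry,) = log.entries
    assert entry.action == SuggestedCorrection.REASSIGN_CHARGE


def test_ambiguous_suggestion_left_untouched(ptm_table):
    ds = _dataset([_target_psm("a", "PEPTIDEKPEPTIDEK", [], 3, annotated_charge=2)])
    reports = detect_issues(validate_delta_mz(ds), ds, ptm_table)
    # corrupt the suggestion so no charge can fit
    reports[0].details["suggested_charges"]["a"] = 7
    corrected, log = reassign_wrong_charges(ds, reports)
    (_, psm), = iter_psms(corrected)
    assert psm.charge_claimed == 2
    (entry,) = log.entries
    assert entry.action == SuggestedCorrection.ANNOTATE_ONLY


def test_full_pipeline_recovery_and_audit(ptm_table):
    """Inject iii+iv+v, detect, correct: ground truth restored, deltas never
    worsened, and every mutation matches exactly one log entry."""
    batch = generate(
        GeneratorConfig(
            seed=99, n_studies=1, samples_per_study=3, psms_per_sample=60,
            defect_spec={
                "iii_double_label": 0.3,
                "iv_zero_charge": 0.3,
                "v_wrong_charge": 0.3,
            },
        )
    )
    ds = batch.datasets[0]
    target, _ = convert_study(ds, ptm_table)
    records = validate_delta_mz(target)
    before = {(r.sample_id, r.psm_ref): r.delta_mz for r in records}
    reports = detect_issues(records, target, ptm_table)
    corrected, entries = _apply_corrections(target, reports, QcConfig())

    mutated_refs = set()
    for sample, psm in iter_psms(corrected):
        truth = batch.ground_truth.psms[(ds.study_id, sample.sample_id, psm.peptide_id)]
        assert psm.charge_claimed == truth.true_charge
        assert sorted((m.position, round(m.mono_delta, 4)) for m in psm.modifications) \
            == sorted((p, round(d, 4)) for p, _a, d in truth.true_mods)
        orig = next(
            p for s, p in iter_psms(target)
            if s.sample_id == sample.sample_id and p.peptide_id == psm.peptide_id
        )
        if (psm.charge_claimed != orig.charge_claimed
                or psm.modifications != orig.modifications):
            mutated_refs.add(f"{sample.sample_id}/{psm.peptide_id}")

    for rec in validate_delta_mz(corrected):
        prior = before[(rec.sample_id, rec.psm_ref)]
        if rec.delta_mz is not None and prior is not None:
            assert abs(rec.delta_mz) <= abs(prior) + 1e-12

    mutation_entries = [e for e in entries
                        if e.action != SuggestedCorrection.ANNOTATE_ONLY]
    logged_refs = {e.ref.split("@")[0] for e in mutation_entries}
    assert logged_refs == mutated_refs
    # exactly one entry per mutated site/psm
    refs = [e.ref for e in mutation_entries]
    assert len(refs) == len(set(refs))
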