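"""Conversion rules: unit mapping, expansion, replication, relabeling."""

import copy

import pytest

from idmigrate.convert import (
    ConversionError,
    convert_study,
    expand_protein_inference,
    replicate_multi_engine,
)
from idmigrate.formats.model import (
    PeptideIdentification,
    ProteinMapping,
    Sample,
    Spectrum,
    StudyDataset,
    iter_psms,
    peptide_species_key,
)
from idmigrate.qc import cross_validate_counts
from idmigrate.synthgen import GeneratorConfig, generate


def _psm(pid, mappings, seq="PEPTIDEK"):
    return PeptideIdentification(
        peptide_id=pid,
        sequence=seq,
        spectrum_ref=f"sp_{pid}",
        charge_claimed=2,
        protein_mappings=[ProteinMapping(a, e) for a, e in mappings],
    )


def test_one_study_three_samples_becomes_one_project_three_experiments(ptm_table):
    ds = StudyDataset(
        shape="source",
        study_id="PSE108",
        samples=[Sample(sample_id=f"S{i}", peptides=[_psm(f"p{i}", [("P1", "Mascot")])])
                 for i in range(3)],
    )
    target, report = convert_study(ds, ptm_table)
    assert target.shape == "target" and len(target.samples) == 3
    assert report.projects_out == report.studies_in == 1
    assert report.experiments_out == report.samples_in == 3


def test_identification_free_sample_converts_to_spectra_only(ptm_table):
    spectra = [Spectrum(f"s{i}", f"s{i}", 400.0 + i, 2) for i in range(10)]
    ds = StudyDataset(
        shape="source", study_id="S",
        samples=[Sample(sample_id="empty", spectra=spectra)],
    )
    target, report = convert_study(ds, ptm_table)
    assert target.samples[0].proteins == []
    assert len(target.samples[0].spectra) == 10
    assert report.peptide_items_created == 0


def test_peptide_mapped_to_k_proteins_yields_k_identical_items():
    per_engine = expand_protein_inference(
        [_psm("p1", [("A", "Mascot"), ("B", "Mascot"), ("C", "Mascot")])]
    )
    proteins = replicate_multi_engine(per_engine)
    assert [p.accession for p in proteins] == ["A", "B", "C"]
    items = [p.peptides[0] for p in proteins]
    assert all(i.sequence == items[0].sequence for i in items)
    assert all(i.spectrum_ref == items[0].spectrum_ref for i in items)
    assert all(i.modifications == items[0].modifications for i in items)


def test_total_items_equals_mapping_pair_count():
    psms = [_psm(f"p{i}", [(f"A{i}", "E1"), (f"B{i}", "E1")]) for i in range(5)]
    proteins = replicate_multi_engine(expand_protein_inference(psms))
    assert sum(len(p.peptides) for p in proteins) == 10


def test_orphan_identification_rejected():
    with pytest.raises(ConversionError, match="orphan"):
        expand_protein_inference([_psm("p1", [])])


def test_protein_from_n_engines_appears_n_times():
    engines = ["Mascot", "SEQUEST", "X!Tandem", "OMSSA"]
    psms = [_psm("p1", [("P", e) for e in engines])]
    proteins = replicate_multi_engine(expand_protein_inference(psms))
    assert [p.accession for p in proteins] == ["P"] * 4
    assert sorted(p.search_engine for p in proteins) == sorted(engines)


def test_partial_engine_overlap_counts_pairs():
    psms = [
        _psm("p1", [("P1", "A"), ("P1", "B")]),
        _psm("p2", [("P2", "A")]),
    ]
    proteins = replicate_multi_engine(expand_protein_inference(psms))
    assert len(proteins) == 3  # (P1,A), (P1,B), (P2,A)


def test_single_engine_list_unchanged():
    psms = [_psm("p1", [("P1", "A")]), _psm("p2", [("P2", "A")])]
    proteins = replicate_multi_engine(expand_protein_inference(psms))
    assert [(p.accession, p.search_engine) for p in proteins] == [("P1", "A"), ("P2", "A")]


def test_unlabeled_engine_rejected():
    with pytest.raises(ConversionError, match="unlabeled"):
        expand_protein_inference([_psm("p1", [("P1", "")])])


def test_relabeling_preserves_mass_deltas(clean_batch, ptm_table):
    source = clean_batch.datasets[0]
    target, report = convert_study(source, ptm_table)
    assert report.unmapped_ptms == []
    src_mods = {
        psm.peptide_id: sorted((m.position, m.mono_delta) for m in psm.modifications)
        for _, psm in iter_psms(source)
    }
    for _, psm in iter_psms(target):
        assert all(m.accession.startswith("MOD:") for m in psm.modifications)
        assert (
            sorted((m.position, m.mono_delta) for m in psm.modifications)
            == src_mods[psm.peptide_id]
        )


def test_relabeling_is_idempotent(clean_batch, ptm_table):
    """Converting an already-PSI-MOD-labeled dataset changes no deltas."""
    source = clean_batch.datasets[0]
    once, _ = convert_study(source, ptm_table)
    relabeled_source = copy.deepcopy(source)
    for _, psm in iter_psms(relabeled_source):
        for site, ref in zip(
            psm.modifications,
            next(
                p for _, p in iter_psms(once) if p.peptide_id == psm.peptide_id
            ).modifications,
        ):
            site.accession = ref.accession
    twice, report = convert_study(relabeled_source, ptm_table)
    for (_, a), (_, b) in zip(iter_psms(once), iter_psms(twice)):
        assert [m.mono_delta for m in a.modifications] == [
            m.mono_delta for m in b.modifications
        ]


def test_unmapped_accession_carried_through_and_reported(ptm_table):
    from idmigrate.formats.model import ModificationSite

    psm = _psm("p1", [("P1", "E1")])
    psm.modifications = [ModificationSite(1, "UNIMOD:99999", 12.5)]
    ds = StudyDataset(shape="source", study_id="S",
                      samples=[Sample(sample_id="s1", peptides=[psm])])
    target, report = convert_study(ds, ptm_table)
    site = target.samples[0].proteins[0].peptides[0].modifications[0]
    assert site.accession == "UNIMOD:99999" and site.mono_delta == 12.5
    assert report.unmapped_ptms == ["UNIMOD:99999"]


def test_conservation_over_random_datasets(ptm_table):
    """Species and (protein, engine) identifications are conserved; item
    totals equal the brute-force mapping-pair count."""
    for seed in range(10):
        batch = generate(
            GeneratorConfig(seed=seed, n_studies=1, samples_per_study=2,
                            psms_per_sample=20)
        )
        source = batch.datasets[0]
        target, report = convert_study(source, ptm_table)
        assert cross_validate_counts(source, target).passed
        n_pairs = sum(
            len(psm.protein_mappings) for _, psm in iter_psms(source)
        )
        n_items = sum(
            len(p.peptides) for s in target.samples for p in s.proteins
        )
        assert n_items == n_pairs == report.peptide_items_created
        src_species = {
            (s.sample_id,) + peptide_species_key(p) for s, p in iter_psms(source)
        }
        tgt_species = {
            (s.sample_id,) + peptide_species_key(p) for s, p in iter_psms(target)
        }
        assert src_species == tgt_species
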