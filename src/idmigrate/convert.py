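"""Source → target model transformation.

Four rules govern the conversion:

1. **Unit mapping** — each source study becomes one target project; each
   sample becomes one experiment (counts are conserved and reported).
2. **Protein-inference expansion** — the source model stores explicit
   peptide→protein many-to-many mappings; the target model nests peptide
   items under protein items. A peptide mapped to *k* proteins therefore
   yields exactly *k* content-identical peptide items, one under each
   protein. No grouping or parsimony inference is attempted.
3. **Multi-engine replication** — when *n* search engines redundantly
   report the same protein accession, the accession appears *n* times in
   the target, each instance tagged with its engine; results are never
   merged or rescored.
4. **Vocabulary and metadata carry-over** — modification accessions are
   re-labelled from the Unimod-style to the PSI-MOD-style vocabulary
   (mass deltas unchanged; unmapped accessions are carried through
   verbatim and reported), and free-text metadata fields are copied
   verbatim.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from idmigrate.formats.model import (
    PeptideIdentification,
    ProteinIdentification,
    Sample,
    StudyDataset,
)
from idmigrate.ptm import PtmTable, UnmappedPtmError

__all__ = [
    "ConversionError",
    "ConversionReport",
    "convert_study",
    "expand_protein_inference",
    "replicate_multi_engine",
]


class ConversionError(ValueError):
    pass


@dataclass
class ConversionReport:
    """Accounting of one conversion run.

    Invariants: ``projects_out == studies_in`` and
    ``experiments_out == samples_in`` — the unit mapping is 1:1.
    """

    studies_in: int = 0
    projects_out: int = 0
    samples_in: int = 0
    experiments_out: int = 0
    peptide_items_created: int = 0
    engine_replications: int = 0
    unmapped_ptms: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "studies_in": self.studies_in,
            "projects_out": self.projects_out,
            "samples_in": self.samples_in,
            "experiments_out": self.experiments_out,
            "peptide_items_created": self.peptide_items_created,
            "engine_replications": self.engine_replications,
            "unmapped_ptms": list(self.unmapped_ptms),
        }


def _peptide_item(psm: PeptideIdentification) -> PeptideIdentification:
    """A deep copy of the PSM without its source-shape protein mappings."""
    item = copy.deepcopy(psm)
    item.protein_mappings = []
    return item


def expand_protein_inference(
    peptides: list[PeptideIdentification],
) -> dict[str, list[ProteinIdentification]]:
    """Expand peptide→protein mappings into per-engine protein items.

    Returns engine → protein items (engines and proteins in first-appearance
    order). A peptide with *k* mapping records contributes *k* peptide-item
    copies. A peptide with no mapping is an orphan identification and an
    error; so is a mapping without an engine label.
    """
    per_engine: dict[str, dict[str, ProteinIdentification]] = {}
    for psm in peptides:
        if not psm.protein_mappings:
            raise ConversionError(
                f"orphan identification: PSM {psm.peptide_id!r} maps to no protein"
            )
        for mapping in psm.protein_mappings:
            if not mapping.engine:
                raise ConversionError(
                    f"unlabeled engine result for PSM {psm.peptide_id!r} "
                    f"(protein {mapping.accession!r})"
                )
            proteins = per_engine.setdefault(mapping.engine, {})
            protein = proteins.get(mapping.accession)
            if protein is None:
                protein = ProteinIdentification(
                    accession=mapping.accession, search_engine=mapping.engine
                )
                proteins[mapping.accession] = protein
            protein.peptides.append(_peptide_item(psm))
    return {engine: list(protein_map.values()) for engine, protein_map in per_engine.items()}


def replicate_multi_engine(
    per_engine: dict[str, list[ProteinIdentification]],
) -> list[ProteinIdentification]:
    """Flatten per-engine protein lists, keeping every redundant instance.

    A protein reported by *n* engines appears *n* times, each instance
    tagged with its engine; nothing is merged or rescored. Peptide sets are
    kept per engine instance.
    """
    out: list[ProteinIdentification] = []
    for engine, proteins in per_engine.items():
        if not engine:
            raise ConversionError("unlabeled engine result set")
        for protein in proteins:
            if protein.search_engine != engine:
                protein = copy.deepcopy(protein)
                protein.search_engine = engine
            out.append(protein)
    return out


def _relabel_modifications(
    psm: PeptideIdentification, ptm_table: PtmTable, unmapped: list[str]
) -> None:
    for site in psm.modifications:
        if site.accession.startswith("MOD:"):
            continue  # already target-vocabulary; mass delta untouched
        try:
            mapping = ptm_table.map_unimod_to_psimod(site.accession)
        except UnmappedPtmError:
            if site.accession not in unmapped:
                unmapped.append(site.accession)
            continue  # carried through verbatim with its mass delta
        site.accession = mapping.psimod_acc


def convert_study(
    dataset: StudyDataset, ptm_table: PtmTable
) -> tuple[StudyDataset, ConversionReport]:
    """Convert one source-shape study into one target-shape project.

    Each sample becomes one experiment; identifications are expanded and
    replicated per the module rules; modification accessions re-labelled;
    metadata, taxa, engine lists and MGF references carried verbatim.
    Spectra attached to the source samples are shared with the result.

    Raises :class:`ConversionError` on a non-source input, an orphan
    identification, or (when spectra are attached) an unresolvable
    spectrum reference.
    """
    if dataset.shape != "source":
        raise ConversionError(f"expected source shape, got {dataset.shape!r}")
    report = ConversionReport(studies_in=1, projects_out=1)
    experiments = []
    for sample in dataset.samples:
        if sample.spectra:
            index = sample.spectrum_index()
            for psm in sample.peptides:
                if psm.spectrum_ref not in index:
                    raise ConversionError(
                        f"PSM {psm.peptide_id!r} in sample {sample.sample_id!r} "
                        f"references unresolvable spectrum {psm.spectrum_ref!r}"
                    )
        report.samples_in += 1
        relabeled = []
        for psm in sample.peptides:
            psm = copy.deepcopy(psm)
            _relabel_modifications(psm, ptm_table, report.unmapped_ptms)
            relabeled.append(psm)
        if relabeled:
            per_engine = expand_protein_inference(relabeled)
            proteins = replicate_multi_engine(per_engine)
        else:
            proteins = []
        report.peptide_items_created += sum(len(p.peptides) for p in proteins)
        accessions = {p.accession for p in proteins}
        report.engine_replications += len(proteins) - len(accessions)
        experiments.append(
            Sample(
                sample_id=sample.sample_id,
                metadata=dict(sample.metadata),
                taxa=list(sample.taxa),
                engines=list(sample.engines),
                mgf_files=list(sample.mgf_files),
                spectra=sample.spectra,
                proteins=proteins,
            )
        )
        report.experiments_out += 1
    target = StudyDataset(shape="target", study_id=dataset.study_id, samples=experiments)
    return target, report
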