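"""Audited corrections for the correctable defect classes.

Three corrections are applied, always on the target-shape dataset after
conversion (the workflow order is convert → validate → correct):

* **Double label (class iii)** — at a site carrying both forms of one
  labelling reagent, the form injected as a *fixed annotation* is removed
  and the reported one kept. When both forms were reported by the
  submitter there is no mechanical basis for choosing: nothing is changed
  and the site is logged for manual review.
* **Zero charge (class iv)** — the charge is recovered as the theoretical
  mass over (measured m/z − proton mass), rounded to the nearest integer.
  Spectra identified by no peptide keep charge 0: with no sequence there
  is no theoretical mass to divide.
* **Wrong charge (class v)** — the charge suggested by the exhaustive
  alternative-charge scan replaces the annotated one, but only when the
  post-reassignment |delta| falls inside the acceptance window; an
  ambiguous PSM is left untouched and logged.

Missing-modification classes (i and ii) are detect-and-annotate only by
default: inserting modification sites risks introducing new errors, and
site placement is ambiguous whenever several candidate residues exist. An
opt-in helper adds a missing methionine oxidation only when the peptide
contains exactly one Met.

Every mutation (and every deliberate non-mutation) lands in exactly one
:class:`CorrectionLog` entry — the audit trail handed back with the
corrected dataset. All corrections return a modified deep copy; inputs are
never mutated. A corrected PSM's |delta| never increases, and untouched
PSMs are bit-identical.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable

from idmigrate.formats.model import (
    ModOrigin,
    ModificationSite,
    PeptideIdentification,
    Sample,
    StudyDataset,
    iter_psms,
)
from idmigrate.masscalc import (
    DEFAULT_CONSTANTS,
    MassError,
    PhysicalConstants,
    infer_charge,
    peptide_mass,
    theoretical_mz,
)
from idmigrate.ptm import PtmTable, load_default_table
from idmigrate.qc import IssueClass, IssueReport, QcConfig, SuggestedCorrection

__all__ = [
    "CorrectionEntry",
    "CorrectionLog",
    "remove_fixed_labels",
    "fix_zero_charges",
    "reassign_wrong_charges",
    "add_missing_metox",
]


@dataclass
class CorrectionEntry:
    ref: str  # "<sample>/<psm>" or "<sample>/<psm>@<position>" for sites
    issue_class: IssueClass
    action: SuggestedCorrection
    before: object
    after: object
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "ref": self.ref,
            "issue_class": self.issue_class.value,
            "action": self.action.value,
            "before": self.before,
            "after": self.after,
            "note": self.note,
        }


@dataclass
class CorrectionLog:
    entries: list[CorrectionEntry] = field(default_factory=list)

    def append(self, entry: CorrectionEntry) -> None:
        self.entries.append(entry)

    def mutations(self) -> list[CorrectionEntry]:
        return [e for e in self.entries if e.action != SuggestedCorrection.ANNOTATE_ONLY]

    def as_dicts(self) -> list[dict]:
        return [e.as_dict() for e in self.entries]


def _psm_copies(sample: Sample, psm_ref: str) -> list[PeptideIdentification]:
    """All content-identical copies of one PSM within a sample (a PSM
    duplicated under several protein items must be mutated everywhere)."""
    if sample.peptides:
        return [p for p in sample.peptides if p.peptide_id == psm_ref]
    return [
        p
        for protein in sample.proteins
        for p in protein.peptides
        if p.peptide_id == psm_ref
    ]


def _sample_map(dataset: StudyDataset) -> dict[str, Sample]:
    return {s.sample_id: s for s in dataset.samples}


def _set_charge(sample: Sample, psm_ref: str, charge: int) -> None:
    copies = _psm_copies(sample, psm_ref)
    for p in copies:
        p.charge_claimed = charge
    index = sample.spectrum_index()
    spectrum = index.get(copies[0].spectrum_ref) if copies else None
    if spectrum is not None:
        spectrum.precursor_charge = charge


def _mod_repr(sites: Iterable[ModificationSite]) -> list[dict]:
    return [
        {
            "position": s.position,
            "accession": s.accession,
            "mono_delta": s.mono_delta,
            "origin": s.origin.value,
        }
        for s in sites
    ]


def remove_fixed_labels(
    dataset: StudyDataset,
    conflicts: dict[str, dict[str, list[tuple]]] | None = None,
    ptm_table: PtmTable | None = None,
) -> tuple[StudyDataset, CorrectionLog]:
    """Remove label forms injected as fixed annotations at conflicted sites.

    ``conflicts`` maps sample_id → psm_ref → conflict triples, as produced
    by class-iii detection; when omitted, conflicts are recomputed from the
    dataset with ``ptm_table``. At each conflicted position the site whose
    origin is ``fixed_annotation`` is dropped and the reported one kept;
    when both are reported nothing changes and an annotate-only entry
    records the site.
    """
    dataset = copy.deepcopy(dataset)
    log = CorrectionLog()
    table = ptm_table or load_default_table()
    if conflicts is None:
        conflicts = {}
        for sample, psm in iter_psms(dataset):
            found = table.find_label_conflicts(psm)
            if found:
                conflicts.setdefault(sample.sample_id, {})[psm.peptide_id] = [
                    (pos, light.unimod_acc, heavy.unimod_acc)
                    for pos, light, heavy in found
                ]
    samples = _sample_map(dataset)
    for sample_id, per_psm in conflicts.items():
        sample = samples[sample_id]
        for psm_ref, triples in per_psm.items():
            copies = _psm_copies(sample, psm_ref)
            if not copies:
                continue
            for pos, _light_acc, _heavy_acc in triples:
                site_group = [
                    s
                    for s in copies[0].modifications
                    if s.position == pos
                    and (m := table.resolve(s.accession)) is not None
                    and m.label_family
                ]
                fixed = [s for s in site_group if s.origin == ModOrigin.FIXED_ANNOTATION]
                ref = f"{sample_id}/{psm_ref}@{pos}"
                if not fixed:
                    log.append(
                        CorrectionEntry(
                            ref=ref,
                            issue_class=IssueClass.III_DOUBLE_LABEL,
                            action=SuggestedCorrection.ANNOTATE_ONLY,
                            before=_mod_repr(site_group),
                            after=_mod_repr(site_group),
                            note="both label forms reported by submitter; "
                            "no mechanical correction",
                        )
                    )
                    continue
                before = _mod_repr(copies[0].modifications)
                drop = {(s.position, s.accession, s.origin) for s in fixed}
                for p in copies:
                    p.modifications = [
                        s
                        for s in p.modifications
                        if (s.position, s.accession, s.origin) not in drop
                    ]
                log.append(
                    CorrectionEntry(
                        ref=ref,
                        issue_class=IssueClass.III_DOUBLE_LABEL,
                        action=SuggestedCorrection.REMOVE_FIXED_LABEL,
                        before=before,
                        after=_mod_repr(copies[0].modifications),
                    )
                )
    return dataset, log


def fix_zero_charges(
    dataset: StudyDataset,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    max_charge: int = 8,
) -> tuple[StudyDataset, CorrectionLog]:
    """Infer every identified PSM's missing (zero) precursor charge.

    The charge is never guessed: when inference fails (measured m/z at or
    below the proton mass, or an implausibly high ratio) the PSM stays at
    charge 0 with an annotate-only log entry. Spectra referenced by no PSM
    are untouched.
    """
    dataset = copy.deepcopy(dataset)
    log = CorrectionLog()
    for sample in dataset.samples:
        index = sample.spectrum_index()
        seen: set[str] = set()
        for psm in _distinct_psms(sample):
            if psm.charge_claimed != 0 or psm.peptide_id in seen:
                continue
            seen.add(psm.peptide_id)
            spectrum = index.get(psm.spectrum_ref)
            if spectrum is None:
                continue
            mass = peptide_mass(
                psm.sequence,
                [(m.position, m.mono_delta) for m in psm.modifications],
                constants,
            )
            ref = f"{sample.sample_id}/{psm.peptide_id}"
            try:
                charge = infer_charge(
                    mass, spectrum.precursor_mz, constants, max_charge=max_charge
                )
            except MassError as exc:
                log.append(
                    CorrectionEntry(
                        ref=ref,
                        issue_class=IssueClass.IV_ZERO_CHARGE,
                        action=SuggestedCorrection.ANNOTATE_ONLY,
                        before=0,
                        after=0,
                        note=f"charge not inferable: {exc}",
                    )
                )
                continue
            _set_charge(sample, psm.peptide_id, charge)
            log.append(
                CorrectionEntry(
                    ref=ref,
                    issue_class=IssueClass.IV_ZERO_CHARGE,
                    action=SuggestedCorrection.INFER_CHARGE,
                    before=0,
                    after=charge,
                )
            )
    return dataset, log


def _distinct_psms(sample: Sample) -> Iterable[PeptideIdentification]:
    if sample.peptides:
        return list(sample.peptides)
    seen: set[str] = set()
    out = []
    for protein in sample.proteins:
        for psm in protein.peptides:
            if psm.peptide_id not in seen:
                seen.add(psm.peptide_id)
                out.append(psm)
    return out


def reassign_wrong_charges(
    dataset: StudyDataset,
    reports: Iterable[IssueReport],
    config: QcConfig | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> tuple[StudyDataset, CorrectionLog]:
    """Apply the alternative charges suggested by class-v reports.

    The suggested charge is accepted only when it brings |delta| inside
    the acceptance window (recomputed here, never trusted from the
    report); otherwise the PSM is left unchanged with an annotate-only
    entry.
    """
    config = config or QcConfig()
    dataset = copy.deepcopy(dataset)
    log = CorrectionLog()
    samples = _sample_map(dataset)
    for report in reports:
        if report.issue_class != IssueClass.V_WRONG_CHARGE:
            continue
        suggested: dict[str, int] = report.details.get("suggested_charges", {})
        sample = samples.get(report.sample_id)
        if sample is None:
            continue
        index = sample.spectrum_index()
        for psm_ref in report.psm_refs:
            new_z = suggested.get(psm_ref)
            if new_z is None:
                continue
            copies = _psm_copies(sample, psm_ref)
            if not copies:
                continue
            psm = copies[0]
            spectrum = index.get(psm.spectrum_ref)
            if spectrum is None:
                continue
            mass = peptide_mass(
                psm.sequence,
                [(m.position, m.mono_delta) for m in psm.modifications],
                constants,
            )
            delta_after = spectrum.precursor_mz - theoretical_mz(mass, new_z, constants)
            ref = f"{sample.sample_id}/{psm_ref}"
            if abs(delta_after) >= config.charge_match_tol:
                log.append(
                    CorrectionEntry(
                        ref=ref,
                        issue_class=IssueClass.V_WRONG_CHARGE,
                        action=SuggestedCorrection.ANNOTATE_ONLY,
                        before=psm.charge_claimed,
                        after=psm.charge_claimed,
                        note=f"no charge brings |delta m/z| below "
                        f"{config.charge_match_tol} Th",
                    )
                )
                continue
            before = psm.charge_claimed
            _set_charge(sample, psm_ref, new_z)
            log.append(
                CorrectionEntry(
                    ref=ref,
                    issue_class=IssueClass.V_WRONG_CHARGE,
                    action=SuggestedCorrection.REASSIGN_CHARGE,
                    before=before,
                    after=new_z,
                )
            )
    return dataset, log


def add_missing_metox(
    dataset: StudyDataset,
    reports: Iterable[IssueReport],
    ptm_table: PtmTable | None = None,
) -> tuple[StudyDataset, CorrectionLog]:
    """Opt-in: add a missing oxidation for class-ii PSMs with exactly one Met.

    A peptide with several methionines is left annotate-only — the site
    cannot be placed unambiguously from the precursor delta alone.
    """
    table = ptm_table or load_default_table()
    mapping = table.resolve("UNIMOD:35")
    if mapping is None:
        raise ValueError("modification table lacks an oxidation entry")
    dataset = copy.deepcopy(dataset)
    log = CorrectionLog()
    samples = _sample_map(dataset)
    for report in reports:
        if report.issue_class != IssueClass.II_MISSING_METOX:
            continue
        sample = samples.get(report.sample_id)
        if sample is None:
            continue
        for psm_ref in report.psm_refs:
            copies = _psm_copies(sample, psm_ref)
            if not copies:
                continue
            psm = copies[0]
            met_positions = [i + 1 for i, aa in enumerate(psm.sequence) if aa == "M"]
            ref = f"{sample.sample_id}/{psm_ref}"
            if len(met_positions) != 1:
                log.append(
                    CorrectionEntry(
                        ref=ref,
                        issue_class=IssueClass.II_MISSING_METOX,
                        action=SuggestedCorrection.ANNOTATE_ONLY,
                        before=_mod_repr(psm.modifications),
                        after=_mod_repr(psm.modifications),
                        note=f"{len(met_positions)} Met residues; "
                        "site placement ambiguous",
                    )
                )
                continue
            before = _mod_repr(psm.modifications)
            site = ModificationSite(
                position=met_positions[0],
                accession=mapping.psimod_acc,
                mono_delta=mapping.mono_delta,
                origin=ModOrigin.FIXED_ANNOTATION,
            )
            for p in copies:
                p.modifications.append(
                    ModificationSite(site.position, site.accession,
                                     site.mono_delta, site.origin)
                )
            log.append(
                CorrectionEntry(
                    ref=ref,
                    issue_class=IssueClass.II_MISSING_METOX,
                    action=SuggestedCorrection.ADD_MODIFICATION,
                    before=before,
                    after=_mod_repr(psm.modifications),
                    note="oxidation added at the single Met (opt-in)",
                )
            )
    return dataset, log
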