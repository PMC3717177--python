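"""Delta-m/z validation, defect detection, count cross-validation, summary.

The central diagnostic is the precursor **delta m/z**: observed precursor
m/z minus the m/z computed from the identified sequence, its modification
annotations (reported *and* fixed), and the annotated charge. On a clean
PSM it is near zero; systematic offsets identify five recurrent defect
classes in migrated identification data:

i.   *No modifications reported at all* — a scope (sample) carries zero
     modification sites, yet a fraction of its PSMs shows deltas matching
     known single-modification signatures ``+delta_mod / z``.
ii.  *Missing methionine-oxidation annotations* — in a scope that does
     report modifications, a Met-containing PSM without an oxidation
     annotation sits at ``+15.994915 / z``.
iii. *Double isotopic label* — the light form of a labelling reagent was
     injected as a fixed annotation next to the reported heavy form on the
     same residue; detectable structurally (two same-family labels at one
     position) or by a ``-(light delta) / z`` offset.
iv.  *Zero precursor charge* — the charge was never recorded; no delta can
     be computed and the PSM is routed to charge inference.
v.   *Wrong precursor charge* — the delta is an outlier, but some other
     charge z' explains the precursor almost exactly; z' is suggested by
     exhaustive scan.

A PSM whose delta is already explained by a class-ii or class-iii
signature is excluded from the class-v scan (the signature accounts for
the outlier); classes may otherwise co-occur freely, within one sample and
even on one PSM (e.g. a zero charge on a double-labelled peptide).

Count cross-validation defines migration consistency over the quantities
the conversion is required to conserve: spectra, distinct peptide species
(label-invariant), and distinct (protein accession, engine) identifications
per sample. Raw peptide-item counts are deliberately *not* compared — the
protein-inference expansion duplicates items by design.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

from idmigrate.formats.model import (
    PeptideIdentification,
    Sample,
    StudyDataset,
    iter_psms,
    peptide_species_key,
)
from idmigrate.masscalc import (
    DEFAULT_CONSTANTS,
    PhysicalConstants,
    peptide_mass,
    theoretical_mz,
)
from idmigrate.ptm import PtmTable, load_default_table

__all__ = [
    "QcError",
    "QcConfig",
    "DeltaMzRecord",
    "IssueClass",
    "SuggestedCorrection",
    "IssueReport",
    "CountCheck",
    "CountCrossValidation",
    "SummaryStats",
    "validate_delta_mz",
    "detect_issues",
    "cross_validate_counts",
    "summarize",
]

_METOX_DELTA = 15.994915  # monoisotopic O; fallback when no table is given


class QcError(ValueError):
    pass


@dataclass
class QcConfig:
    """Validator thresholds (Th unless noted).

    ``tol`` — half-width for matching a delta against a modification
    signature; ``outlier_tol`` — |delta| above which a PSM counts as an
    outlier; ``charge_match_tol`` — acceptance window for an alternative
    charge to *explain* an outlier (wider than ``tol``: alternative charges
    are separated by many Th, so the window costs no specificity but
    tolerates precursor noise); ``min_frac`` — fraction of signature-matching
    PSMs required to call a zero-modification scope class i;
    ``severity_threshold`` — fraction of affected PSMs above which a
    correction (rather than an annotation) is suggested.
    """

    tol: float = 0.01
    outlier_tol: float = 0.1
    charge_match_tol: float = 0.05
    max_charge: int = 8
    min_frac: float = 0.05
    severity_threshold: float = 0.5


@dataclass
class DeltaMzRecord:
    """Delta-m/z outcome for one PSM.

    ``delta_mz`` and ``theoretical_mz`` are ``None`` when the annotated
    charge is zero (class iv): without a charge there is no theoretical
    m/z. ``theoretical_mass`` (Da) is always available and is what charge
    inference uses.
    """

    psm_ref: str
    sample_id: str
    observed_mz: float
    theoretical_mass: float
    charge_used: int
    theoretical_mz: float | None
    delta_mz: float | None


class IssueClass(str, enum.Enum):
    I_NO_MODS = "i_no_mods"
    II_MISSING_METOX = "ii_missing_metox"
    III_DOUBLE_LABEL = "iii_double_label"
    IV_ZERO_CHARGE = "iv_zero_charge"
    V_WRONG_CHARGE = "v_wrong_charge"


class SuggestedCorrection(str, enum.Enum):
    REMOVE_FIXED_LABEL = "remove_fixed_label"
    INFER_CHARGE = "infer_charge"
    REASSIGN_CHARGE = "reassign_charge"
    ANNOTATE_ONLY = "annotate_only"
    # log-only action for the opt-in oxidation helper; never suggested
    ADD_MODIFICATION = "add_modification"


@dataclass
class IssueReport:
    """One detected defect class within one sample scope."""

    issue_class: IssueClass
    study_id: str
    sample_id: str
    psm_refs: list[str]
    evidence: list[DeltaMzRecord]
    suggested_correction: SuggestedCorrection
    severity: float  # fraction of the scope's PSMs affected, in [0, 1]
    details: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "issue_class": self.issue_class.value,
            "study_id": self.study_id,
            "sample_id": self.sample_id,
            "psm_refs": list(self.psm_refs),
            "n_affected": len(self.psm_refs),
            "suggested_correction": self.suggested_correction.value,
            "severity": self.severity,
            "details": self.details,
        }


def report_from_dict(data: dict) -> IssueReport:
    """Rebuild a report from its JSON form (evidence records are not
    serialised and come back empty; corrections recompute deltas anyway)."""
    suggested = data.get("details", {}).get("suggested_charges")
    details = dict(data.get("details", {}))
    if suggested is not None:
        details["suggested_charges"] = {k: int(v) for k, v in suggested.items()}
    return IssueReport(
        issue_class=IssueClass(data["issue_class"]),
        study_id=data["study_id"],
        sample_id=data["sample_id"],
        psm_refs=list(data["psm_refs"]),
        evidence=[],
        suggested_correction=SuggestedCorrection(data["suggested_correction"]),
        severity=float(data["severity"]),
        details=details,
    )


def validate_delta_mz(
    dataset: StudyDataset,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    ptm_table: PtmTable | None = None,  # noqa: ARG001  (interface symmetry)
) -> list[DeltaMzRecord]:
    """Compute one delta-m/z record per distinct PSM of the dataset.

    Spectra must be attached. The theoretical mass includes every annotated
    modification site regardless of origin — a wrongly injected fixed
    annotation therefore *shifts* the delta, which is exactly what makes it
    detectable. PSMs with charge 0 yield a record with no delta, routed to
    class-iv detection.

    Raises :class:`QcError` naming the PSM when a spectrum reference does
    not resolve.
    """
    records = []
    for sample, psm in iter_psms(dataset):
        index = sample.spectrum_index()
        spectrum = index.get(psm.spectrum_ref)
        if spectrum is None:
            raise QcError(
                f"PSM {psm.peptide_id!r} in sample {sample.sample_id!r} "
                f"references unresolvable spectrum {psm.spectrum_ref!r}"
            )
        mass = peptide_mass(
            psm.sequence,
            [(m.position, m.mono_delta) for m in psm.modifications],
            constants,
        )
        if psm.charge_claimed <= 0:
            records.append(
                DeltaMzRecord(
                    psm_ref=psm.peptide_id,
                    sample_id=sample.sample_id,
                    observed_mz=spectrum.precursor_mz,
                    theoretical_mass=mass,
                    charge_used=0,
                    theoretical_mz=None,
                    delta_mz=None,
                )
            )
            continue
        theo = theoretical_mz(mass, psm.charge_claimed, constants)
        records.append(
            DeltaMzRecord(
                psm_ref=psm.peptide_id,
                sample_id=sample.sample_id,
                observed_mz=spectrum.precursor_mz,
                theoretical_mass=mass,
                charge_used=psm.charge_claimed,
                theoretical_mz=theo,
                delta_mz=spectrum.precursor_mz - theo,
            )
        )
    return records


def _suggest(
    default: SuggestedCorrection, severity: float, config: QcConfig
) -> SuggestedCorrection:
    if severity >= config.severity_threshold:
        return default
    return SuggestedCorrection.ANNOTATE_ONLY


def _metox_delta(ptm_table: PtmTable) -> float:
    mapping = ptm_table.resolve("UNIMOD:35")
    return mapping.mono_delta if mapping else _METOX_DELTA


def _has_site_with_delta(psm: PeptideIdentification, delta: float) -> bool:
    return any(abs(m.mono_delta - delta) < 1e-3 for m in psm.modifications)


def _best_alternative_charge(
    rec: DeltaMzRecord,
    mass: float,
    config: QcConfig,
    constants: PhysicalConstants,
) -> tuple[int, float] | None:
    """Exhaustive z' scan; returns (z', delta at z') minimising |delta|."""
    best: tuple[int, float] | None = None
    for z in range(1, config.max_charge + 1):
        if z == rec.charge_used:
            continue
        d = rec.observed_mz - theoretical_mz(mass, z, constants)
        if best is None or abs(d) < abs(best[1]):
            best = (z, d)
    return best


def detect_issues(
    records: Iterable[DeltaMzRecord],
    dataset: StudyDataset,
    ptm_table: PtmTable | None = None,
    config: QcConfig | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> list[IssueReport]:
    """Classify delta-m/z records into the five defect classes.

    Returns one report per (sample, class) with at least one affected PSM;
    a clean dataset yields an empty list.
    """
    config = config or QcConfig()
    ptm_table = ptm_table or load_default_table()
    metox = _metox_delta(ptm_table)
    light_labels = [m for m in ptm_table.label_mappings() if m.label_role == "light"]
    signature_deltas = sorted({m.mono_delta for m in ptm_table})

    by_sample: dict[str, list[DeltaMzRecord]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    psm_index: dict[tuple[str, str], PeptideIdentification] = {}
    sample_index: dict[str, Sample] = {s.sample_id: s for s in dataset.samples}
    for sample, psm in iter_psms(dataset):
        psm_index[(sample.sample_id, psm.peptide_id)] = psm

    reports: list[IssueReport] = []
    for sample_id, recs in by_sample.items():
        total = len(recs)
        if total == 0:
            continue
        psms = {r.psm_ref: psm_index[(sample_id, r.psm_ref)] for r in recs}
        n_sites = sum(len(p.modifications) for p in psms.values())
        explained: set[str] = set()  # PSMs whose outlier a signature accounts for
        # summed mass of fixed-origin label sites at structurally conflicted
        # positions: the class-v scan subtracts it, so a wrong charge stays
        # detectable on a double-labelled PSM
        conflict_fixed_mass: dict[str, float] = {}

        # class iv — zero annotated charge
        zero = [r for r in recs if r.charge_used == 0]
        if zero:
            reports.append(
                _report(
                    IssueClass.IV_ZERO_CHARGE, dataset, sample_id, zero, total,
                    SuggestedCorrection.INFER_CHARGE, config,
                )
            )

        # class iii — double label: structural conflicts, else delta signature
        iii_recs, conflicts_detail = [], {}
        for r in recs:
            psm = psms[r.psm_ref]
            conflicts = ptm_table.find_label_conflicts(psm)
            if conflicts:
                iii_recs.append(r)
                conflicts_detail[r.psm_ref] = [
                    (pos, light.unimod_acc, heavy.unimod_acc)
                    for pos, light, heavy in conflicts
                ]
                positions = {pos for pos, _l, _h in conflicts}
                conflict_fixed_mass[r.psm_ref] = sum(
                    s.mono_delta
                    for s in psm.modifications
                    if s.origin.value == "fixed_annotation" and s.position in positions
                )
                continue
            if r.delta_mz is None:
                continue
            for light in light_labels:
                if _has_site_with_delta(psm, light.mono_delta) and (
                    abs(r.delta_mz + light.mono_delta / r.charge_used) < config.tol
                ):
                    iii_recs.append(r)
                    explained.add(r.psm_ref)
                    break
        if iii_recs:
            reports.append(
                _report(
                    IssueClass.III_DOUBLE_LABEL, dataset, sample_id, iii_recs, total,
                    SuggestedCorrection.REMOVE_FIXED_LABEL, config,
                    details={"conflicts": conflicts_detail},
                )
            )

        if n_sites == 0:
            # class i — no modifications reported anywhere in the scope
            candidates = [
                r for r in recs if r.delta_mz is not None and abs(r.delta_mz) > config.tol
            ]
            matched = [
                r
                for r in candidates
                if any(
                    abs(r.delta_mz - d / r.charge_used) < config.tol
                    for d in signature_deltas
                )
            ]
            if matched and len(matched) / total >= config.min_frac:
                for r in candidates:
                    explained.add(r.psm_ref)
                reports.append(
                    _report(
                        IssueClass.I_NO_MODS, dataset, sample_id, candidates, total,
                        SuggestedCorrection.ANNOTATE_ONLY, config,
                        details={"n_signature_matched": len(matched)},
                    )
                )
        else:
            # class ii — Met-containing PSM missing its oxidation annotation
            ii_recs = []
            for r in recs:
                if r.delta_mz is None:
                    continue
                psm = psms[r.psm_ref]
                n_ox = sum(
                    1 for m in psm.modifications if abs(m.mono_delta - metox) < 1e-3
                )
                if (
                    n_ox < psm.sequence.count("M")  # an unoxidised Met exists
                    and abs(r.delta_mz - metox / r.charge_used) < config.tol
                ):
                    ii_recs.append(r)
                    explained.add(r.psm_ref)
            if ii_recs:
                reports.append(
                    _report(
                        IssueClass.II_MISSING_METOX, dataset, sample_id, ii_recs, total,
                        SuggestedCorrection.ANNOTATE_ONLY, config,
                    )
                )

        # class v — outlier delta explained by an alternative charge. A PSM
        # with a structural label conflict is scanned with the spurious
        # fixed-label mass subtracted (the mass the corrector will restore):
        # wrong charges co-occurring with double labels stay detectable.
        v_recs, suggested = [], {}
        for r in recs:
            if r.delta_mz is None or r.psm_ref in explained:
                continue
            mass = r.theoretical_mass - conflict_fixed_mass.get(r.psm_ref, 0.0)
            delta = r.observed_mz - theoretical_mz(mass, r.charge_used, constants)
            if abs(delta) <= config.outlier_tol:
                continue
            best = _best_alternative_charge(r, mass, config, constants)
            if best is not None and abs(best[1]) < config.charge_match_tol:
                v_recs.append(r)
                suggested[r.psm_ref] = best[0]
        if v_recs:
            reports.append(
                _report(
                    IssueClass.V_WRONG_CHARGE, dataset, sample_id, v_recs, total,
                    SuggestedCorrection.REASSIGN_CHARGE, config,
                    details={"suggested_charges": suggested},
                )
            )
    return reports


def _report(
    issue_class: IssueClass,
    dataset: StudyDataset,
    sample_id: str,
    recs: list[DeltaMzRecord],
    total: int,
    default_correction: SuggestedCorrection,
    config: QcConfig,
    details: dict | None = None,
) -> IssueReport:
    severity = len(recs) / total
    return IssueReport(
        issue_class=issue_class,
        study_id=dataset.study_id,
        sample_id=sample_id,
        psm_refs=[r.psm_ref for r in recs],
        evidence=recs,
        suggested_correction=_suggest(default_correction, severity, config),
        severity=severity,
        details=details or {},
    )


# ---------------------------------------------------------------------------
# count cross-validation and summary statistics

@dataclass
class CountCheck:
    name: str
    source_value: int
    target_value: int

    @property
    def passed(self) -> bool:
        return self.source_value == self.target_value


@dataclass
class CountCrossValidation:
    checks: list[CountCheck]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[CountCheck]:
        return [c for c in self.checks if not c.passed]


def _conserved_counts(dataset: StudyDataset) -> dict[str, int]:
    n_spectra = sum(len(s.spectra) for s in dataset.samples)
    species = set()
    protein_ids = set()
    for sample, psm in iter_psms(dataset):
        species.add((sample.sample_id,) + peptide_species_key(psm))
        for mapping in psm.protein_mappings:  # source shape
            protein_ids.add((sample.sample_id, mapping.accession, mapping.engine))
    for sample in dataset.samples:  # target shape
        for protein in sample.proteins:
            protein_ids.add((sample.sample_id, protein.accession, protein.search_engine))
    return {
        "spectra": n_spectra,
        "peptide_species": len(species),
        "protein_engine_identifications": len(protein_ids),
    }


def cross_validate_counts(
    source: StudyDataset, target: StudyDataset
) -> CountCrossValidation:
    """Check that conversion conserved the counting quantities.

    Consistency is defined over quantities the expansion does not inflate:
    total spectra, distinct peptide species (by spectrum reference,
    sequence and (position, mass delta) modification multiset — invariant
    under vocabulary re-labelling), and distinct (protein accession,
    engine) identifications per sample.
    """
    src, tgt = _conserved_counts(source), _conserved_counts(target)
    return CountCrossValidation(
        checks=[CountCheck(name, src[name], tgt[name]) for name in src]
    )


@dataclass
class SummaryStats:
    """The seven headline counts of a migrated corpus."""

    n_projects: int
    n_experiments: int
    n_distinct_taxa: int
    n_proteins: int
    n_modification_sites: int
    n_peptides: int
    n_spectra: int

    def as_dict(self) -> dict:
        return {
            "n_projects": self.n_projects,
            "n_experiments": self.n_experiments,
            "n_distinct_taxa": self.n_distinct_taxa,
            "n_proteins": self.n_proteins,
            "n_modification_sites": self.n_modification_sites,
            "n_peptides": self.n_peptides,
            "n_spectra": self.n_spectra,
        }


def summarize(datasets: StudyDataset | Iterable[StudyDataset]) -> SummaryStats:
    """Compute the seven summary counts over one or many datasets.

    Taxa are counted over verbatim labels; proteins as distinct (sample,
    accession, engine) identifications; peptides as distinct species per
    sample; modification sites per reported site occurrence on distinct
    PSMs.
    """
    if isinstance(datasets, StudyDataset):
        datasets = [datasets]
    n_projects = n_experiments = n_sites = n_spectra = 0
    taxa: set[str] = set()
    proteins: set[tuple] = set()
    peptides: set[tuple] = set()
    for ds in datasets:
        n_projects += 1
        n_experiments += len(ds.samples)
        for sample in ds.samples:
            taxa.update(sample.taxa)
            n_spectra += len(sample.spectra)
            for protein in sample.proteins:
                proteins.add((ds.study_id, sample.sample_id, protein.accession,
                              protein.search_engine))
        for sample, psm in iter_psms(ds):
            peptides.add((ds.study_id, sample.sample_id) + peptide_species_key(psm))
            n_sites += len(psm.modifications)
            for mapping in psm.protein_mappings:
                proteins.add((ds.study_id, sample.sample_id, mapping.accession,
                              mapping.engine))
    return SummaryStats(
        n_projects=n_projects,
        n_experiments=n_experiments,
        n_distinct_taxa=len(taxa),
        n_proteins=len(proteins),
        n_modification_sites=n_sites,
        n_peptides=len(peptides),
        n_spectra=n_spectra,
    )
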