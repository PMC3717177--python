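"""In-memory domain model shared by the source and target dialects.

A :class:`StudyDataset` is the unit of migration. In the *source* shape it
is a study containing samples, where each sample carries flat peptide
identifications with explicit peptide→protein many-to-many mappings and a
declared search-engine list. In the *target* shape the same study is a
project containing experiments, where identifications are nested: protein
items, each holding copies of the peptide items that support it. The shape
determines which representation is populated — never both.

Spectra live in MGF files referenced by each sample; once attached, each
sample holds its spectra in document order and PSM spectrum references
resolve against them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "Spectrum",
    "ModOrigin",
    "ModificationSite",
    "EngineScore",
    "ProteinMapping",
    "PeptideIdentification",
    "ProteinIdentification",
    "Sample",
    "StudyDataset",
    "DatasetError",
    "iter_psms",
    "peptide_species_key",
]

#: free-text metadata keys carried over verbatim between the two shapes
METADATA_KEYS = (
    "tissue",
    "cell type",
    "disease state",
    "study design",
    "summary",
    "protocol",
)


class DatasetError(ValueError):
    """Structural violation of the dataset model."""


@dataclass
class Spectrum:
    """One MS/MS spectrum: precursor and peak list.

    ``precursor_charge`` 0 means *unknown* — the representable form of the
    missing-charge defect class. Peaks are kept sorted ascending by m/z.
    """

    spectrum_id: str
    title: str
    precursor_mz: float
    precursor_charge: int  # >= 0; 0 = unknown
    peaks: list[tuple[float, float]] = field(default_factory=list)
    rt_seconds: float | None = None
    annotations: dict[str, str] = field(default_factory=dict)  # opaque headers

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise DatasetError(
                f"spectrum {self.spectrum_id!r}: precursor_mz must be > 0"
            )
        if self.precursor_charge < 0:
            raise DatasetError(
                f"spectrum {self.spectrum_id!r}: precursor_charge must be >= 0"
            )
        self.peaks = sorted(self.peaks)


class ModOrigin(str, enum.Enum):
    """Whether a modification site was reported by the submitter or injected
    as a search-time fixed annotation."""

    REPORTED = "reported"
    FIXED_ANNOTATION = "fixed_annotation"


@dataclass
class ModificationSite:
    """A modification at one position: 0 = N-term, 1-based residue index,
    len+1 = C-term. The accession may be Unimod- or PSI-MOD-style."""

    position: int
    accession: str
    mono_delta: float
    origin: ModOrigin = ModOrigin.REPORTED


@dataclass
class EngineScore:
    engine: str
    score: float


@dataclass
class ProteinMapping:
    """One peptide→protein assertion by one search engine (source shape)."""

    accession: str
    engine: str


@dataclass
class PeptideIdentification:
    """One peptide-spectrum match.

    In the source shape ``protein_mappings`` carries the many-to-many
    peptide→protein assertions; in the target shape peptide items are nested
    under protein items and ``protein_mappings`` is empty. ``peptide_id`` is
    stable across the conversion: the copies of one PSM distributed under
    several protein items share it.
    """

    peptide_id: str
    sequence: str
    spectrum_ref: str
    charge_claimed: int  # >= 0; 0 = unknown
    modifications: list[ModificationSite] = field(default_factory=list)
    engine_scores: list[EngineScore] = field(default_factory=list)
    protein_mappings: list[ProteinMapping] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for site in self.modifications:
            if not 0 <= site.position <= n + 1:
                raise DatasetError(
                    f"PSM {self.peptide_id!r}: modification position "
                    f"{site.position} out of range 0..{n + 1}"
                )


@dataclass
class ProteinIdentification:
    """A protein item in the target shape: one accession as reported by one
    search engine, holding the peptide items that support it."""

    accession: str
    search_engine: str
    peptides: list[PeptideIdentification] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.accession:
            raise DatasetError("protein accession must be non-empty")


@dataclass
class Sample:
    """A sample (source) / experiment (target) within one study."""

    sample_id: str
    metadata: dict[str, str] = field(default_factory=dict)
    taxa: list[str] = field(default_factory=list)
    engines: list[str] = field(default_factory=list)
    mgf_files: list[str] = field(default_factory=list)
    spectra: list[Spectrum] = field(default_factory=list)
    peptides: list[PeptideIdentification] = field(default_factory=list)  # source
    proteins: list[ProteinIdentification] = field(default_factory=list)  # target

    def spectrum_index(self) -> dict[str, Spectrum]:
        return {s.spectrum_id: s for s in self.spectra}


@dataclass
class StudyDataset:
    """A study (source) or project (target) with its samples/experiments."""

    shape: str  # "source" | "target"
    study_id: str
    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.shape not in ("source", "target"):
            raise DatasetError(f"shape must be source or target, got {self.shape!r}")
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise DatasetError(f"duplicate sample ids in study {self.study_id!r}")
        for s in self.samples:
            if self.shape == "source" and s.proteins:
                raise DatasetError(
                    f"sample {s.sample_id!r}: nested protein items in source shape"
                )
            if self.shape == "target" and s.peptides:
                raise DatasetError(
                    f"sample {s.sample_id!r}: flat peptide list in target shape"
                )

    def validate_references(self) -> None:
        """Check every PSM's spectrum reference resolves within its sample."""
        for sample in self.samples:
            index = sample.spectrum_index()
            for psm in _sample_psms(sample):
                if psm.spectrum_ref not in index:
                    raise DatasetError(
                        f"PSM {psm.peptide_id!r} in sample "
                        f"{sample.sample_id!r} references unknown spectrum "
                        f"{psm.spectrum_ref!r}"
                    )


def _sample_psms(sample: Sample) -> Iterator[PeptideIdentification]:
    """All distinct PSMs of a sample, document order, one per peptide_id.

    In the target shape a PSM duplicated under several protein items is
    yielded once (first occurrence); the copies are content-identical by the
    conversion contract.
    """
    if sample.peptides:
        yield from sample.peptides
        return
    seen: set[str] = set()
    for prot in sample.proteins:
        for psm in prot.peptides:
            if psm.peptide_id not in seen:
                seen.add(psm.peptide_id)
                yield psm


def iter_psms(dataset: StudyDataset) -> Iterator[tuple[Sample, PeptideIdentification]]:
    """Iterate distinct PSMs across the dataset as (sample, psm) pairs."""
    for sample in dataset.samples:
        for psm in _sample_psms(sample):
            yield sample, psm


def peptide_species_key(psm: PeptideIdentification) -> tuple:
    """Label-invariant identity of a peptide species.

    Conversion re-labels modification accessions between vocabularies, so a
    species is identified by spectrum reference, sequence, and the multiset
    of (position, mass delta) sites — deltas rounded to 1e-4 Da so that the
    key survives re-serialisation.
    """
    mods = tuple(
        sorted((m.position, round(m.mono_delta, 4)) for m in psm.modifications)
    )
    return (psm.spectrum_ref, psm.sequence, mods)
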