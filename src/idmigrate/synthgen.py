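"""Deterministic synthetic source datasets with controlled defect injection.

The generator emulates what a study-centric shotgun-proteomics submission
looks like to the migration machinery: studies of samples, each sample with
free-text metadata, taxon labels, one MGF peak-list file, and flat peptide
identifications carrying peptide→protein mappings and per-engine scores.
Peptide sequences are random tryptic-like strings (C-terminal K/R,
configurable off); precursor m/z values are *computed* from the true
sequence, true modifications and true charge (plus optional Gaussian
noise), so the delta-m/z validator closes exactly over clean output. Peak
lists are decoys — random fragments — because no operation downstream
inspects fragment ions; do not use them to test anything spectral.

Defects are injected per class with configurable penetrance, and every
injection is recorded in a ground-truth table sufficient to score any
detector or corrector:

* class i   — per *sample*: every modification annotation is removed
  (the precursor still reflects the true modified mass);
* class ii  — per eligible PSM: one methionine-oxidation annotation is
  removed;
* class iii — per eligible PSM: the light form of the labelling reagent is
  added as a fixed annotation at every heavy-labelled position;
* class iv  — per PSM: the precursor charge is zeroed;
* class v   — per PSM: the annotated charge is displaced by ±1.

The same seed yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from idmigrate.formats.model import (
    EngineScore,
    ModOrigin,
    ModificationSite,
    PeptideIdentification,
    ProteinMapping,
    Sample,
    Spectrum,
    StudyDataset,
)
from idmigrate.formats.mgf import write_mgf
from idmigrate.formats.xmlio import write_source_xml
from idmigrate.masscalc import DEFAULT_CONSTANTS, peptide_mass, theoretical_mz
from idmigrate.ptm import PtmTable, load_default_table
from idmigrate.qc import IssueClass

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "PsmTruth",
    "GroundTruth",
    "GeneratedBatch",
    "generate",
    "write_batch",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_TRYPTIC_END = "KR"
_TAXON_POOL = (
    "Homo sapiens",
    "Mus musculus",
    "Saccharomyces cerevisiae",
    "Escherichia coli",
    "Synechocystis sp. PCC 6803",
)
_ENGINE_POOL = ("Mascot", "SEQUEST", "X!Tandem", "OMSSA")
_METADATA_TEMPLATES = {
    "tissue": "synthetic tissue {i}",
    "cell type": "synthetic cell line {i}",
    "disease state": "none reported",
    "study design": "shotgun LC-MS/MS, {n} identified spectra per sample",
    "summary": "Synthetic migration test study {i} — µLC–MS/MS at 37 °C",
    "protocol": "Tryptic digest, 1 µg load, 90 min gradient (study {i})",
}


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic batch.

    Defaults describe a small but realistic defect-free corpus: tryptic
    peptides of 7–20 residues at charge 2–3, oxidation on ~30% of
    methionines, phosphorylation on ~10% of S/T/Y, a heavy isotopic label
    on ~20% of cysteines, noise-free precursors, and no injected defects.
    ``defect_spec`` maps issue-class value → penetrance fraction of the
    eligible units (samples for class i, PSMs otherwise).
    """

    seed: int = 0
    n_studies: int = 1
    samples_per_study: int = 3
    psms_per_sample: int = 50
    charge_range: tuple[int, int] = (2, 3)
    peptide_length_range: tuple[int, int] = (7, 20)
    mod_frequency: dict[str, float] = field(
        default_factory=lambda: {
            "UNIMOD:35": 0.30,
            "UNIMOD:21": 0.10,
            "UNIMOD:106": 0.20,
        }
    )
    defect_spec: dict[str, float] = field(default_factory=dict)
    mz_noise_sd: float = 0.0
    tryptic: bool = True
    engines_per_sample_range: tuple[int, int] = (1, 2)
    proteins_per_peptide_max: int = 2
    multi_protein_fraction: float = 0.2
    peaks_per_spectrum: int = 10

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        kwargs = dict(data)
        for key in ("charge_range", "peptide_length_range", "engines_per_sample_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def validate(self, ptm_table: PtmTable) -> None:
        known = {c.value for c in IssueClass}
        for cls_name, p in self.defect_spec.items():
            if cls_name not in known:
                raise ConfigError(f"unknown issue class {cls_name!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"penetrance for {cls_name} must be in [0,1], got {p}")
        if self.defect_spec.get(IssueClass.II_MISSING_METOX.value, 0) > 0:
            if self.mod_frequency.get("UNIMOD:35", 0) <= 0:
                raise ConfigError(
                    "class ii penetrance > 0 requires a positive oxidation "
                    "frequency (UNIMOD:35)"
                )
        if self.defect_spec.get(IssueClass.III_DOUBLE_LABEL.value, 0) > 0:
            heavy = [
                m for m in ptm_table.label_mappings() if m.label_role == "heavy"
            ]
            if not any(self.mod_frequency.get(m.unimod_acc, 0) > 0 for m in heavy):
                raise ConfigError(
                    "class iii penetrance > 0 requires a positive heavy-label "
                    "frequency"
                )
        lo, hi = self.charge_range
        if not 1 <= lo <= hi:
            raise ConfigError(f"invalid charge_range {self.charge_range}")
        lo, hi = self.peptide_length_range
        if not 2 <= lo <= hi:
            raise ConfigError(f"invalid peptide_length_range {self.peptide_length_range}")
        if self.mz_noise_sd < 0:
            raise ConfigError("mz_noise_sd must be >= 0")


@dataclass
class PsmTruth:
    """Ground truth for one generated PSM."""

    study_id: str
    sample_id: str
    psm_id: str
    sequence: str
    true_charge: int
    annotated_charge: int
    true_mods: list[tuple[int, str, float]]
    injected: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "sample_id": self.sample_id,
            "psm_id": self.psm_id,
            "sequence": self.sequence,
            "true_charge": self.true_charge,
            "annotated_charge": self.annotated_charge,
            "true_mods": [list(m) for m in self.true_mods],
            "injected": list(self.injected),
        }


@dataclass
class GroundTruth:
    psms: dict[tuple[str, str, str], PsmTruth] = field(default_factory=dict)

    def affected(self, issue_class: IssueClass) -> set[tuple[str, str, str]]:
        return {
            key
            for key, truth in self.psms.items()
            if issue_class.value in truth.injected
        }

    def as_dicts(self) -> list[dict]:
        return [t.as_dict() for t in self.psms.values()]


@dataclass
class GeneratedBatch:
    datasets: list[StudyDataset]
    ground_truth: GroundTruth
    config: GeneratorConfig


def _random_peptide(rng: np.random.Generator, config: GeneratorConfig) -> str:
    lo, hi = config.peptide_length_range
    length = int(rng.integers(lo, hi + 1))
    letters = [_AA[int(i)] for i in rng.integers(0, len(_AA), length)]
    if config.tryptic:
        letters[-1] = _TRYPTIC_END[int(rng.integers(0, 2))]
    return "".join(letters)


def _draw_mods(
    rng: np.random.Generator,
    sequence: str,
    config: GeneratorConfig,
    ptm_table: PtmTable,
) -> list[tuple[int, str, float]]:
    mods: list[tuple[int, str, float]] = []
    taken: set[int] = set()
    for acc in sorted(config.mod_frequency):
        freq = config.mod_frequency[acc]
        if freq <= 0:
            continue
        mapping = ptm_table.resolve(acc)
        if mapping is None:
            raise ConfigError(f"mod_frequency names unknown accession {acc!r}")
        for i, aa in enumerate(sequence, start=1):
            if aa in mapping.residue_specificity and i not in taken:
                if rng.random() < freq:
                    mods.append((i, acc, mapping.mono_delta))
                    taken.add(i)
    return sorted(mods)


def _decoy_peaks(
    rng: np.random.Generator, n: int
) -> list[tuple[float, float]]:
    mz = np.sort(rng.uniform(100.0, 1500.0, n))
    intensity = rng.uniform(1.0, 1e4, n)
    return [(round(float(m), 6), round(float(i), 6)) for m, i in zip(mz, intensity)]


def generate(
    config: GeneratorConfig, ptm_table: PtmTable | None = None
) -> GeneratedBatch:
    """Generate a batch of source-shape studies with attached spectra.

    Raises :class:`ConfigError` on contradictory settings (e.g. a label
    defect requested while no label is ever generated).
    """
    ptm_table = ptm_table or load_default_table()
    config.validate(ptm_table)
    rng = np.random.default_rng(config.seed)
    heavy_accs = {
        m.unimod_acc for m in ptm_table.label_mappings() if m.label_role == "heavy"
    }
    light_by_family = {
        m.label_family: m
        for m in ptm_table.label_mappings()
        if m.label_role == "light"
    }
    spec = config.defect_spec
    p_i = spec.get(IssueClass.I_NO_MODS.value, 0.0)
    p_ii = spec.get(IssueClass.II_MISSING_METOX.value, 0.0)
    p_iii = spec.get(IssueClass.III_DOUBLE_LABEL.value, 0.0)
    p_iv = spec.get(IssueClass.IV_ZERO_CHARGE.value, 0.0)
    p_v = spec.get(IssueClass.V_WRONG_CHARGE.value, 0.0)

    truth = GroundTruth()
    datasets = []
    for s_idx in range(config.n_studies):
        study_id = f"PSE{s_idx + 1:03d}"
        samples = []
        for j in range(config.samples_per_study):
            sample_id = f"{study_id}_S{j + 1}"
            taxon = _TAXON_POOL[int(rng.integers(0, len(_TAXON_POOL)))]
            n_engines = int(
                rng.integers(
                    config.engines_per_sample_range[0],
                    config.engines_per_sample_range[1] + 1,
                )
            )
            engines = list(_ENGINE_POOL[:n_engines])
            n_proteins = max(3, config.psms_per_sample // 10)
            protein_pool = [f"{sample_id}_P{k + 1:03d}" for k in range(n_proteins)]
            strip_all_mods = rng.random() < p_i

            spectra, peptides = [], []
            for k in range(config.psms_per_sample):
                psm_id = f"{sample_id}_psm{k + 1:05d}"
                spectrum_id = f"{sample_id}_sp{k + 1:05d}"
                sequence = _random_peptide(rng, config)
                true_mods = _draw_mods(rng, sequence, config, ptm_table)
                true_charge = int(
                    rng.integers(config.charge_range[0], config.charge_range[1] + 1)
                )
                mass = peptide_mass(
                    sequence, [(pos, d) for pos, _a, d in true_mods], DEFAULT_CONSTANTS
                )
                mz = theoretical_mz(mass, true_charge, DEFAULT_CONSTANTS)
                if config.mz_noise_sd > 0:
                    mz += float(rng.normal(0.0, config.mz_noise_sd))
                peaks = _decoy_peaks(rng, config.peaks_per_spectrum)

                injected: list[str] = []
                annotated = [
                    ModificationSite(pos, acc, delta, ModOrigin.REPORTED)
                    for pos, acc, delta in true_mods
                ]
                if strip_all_mods:
                    if true_mods:
                        injected.append(IssueClass.I_NO_MODS.value)
                    annotated = []
                else:
                    if p_ii > 0 and any(a == "UNIMOD:35" for _p, a, _d in true_mods):
                        if rng.random() < p_ii:
                            injected.append(IssueClass.II_MISSING_METOX.value)
                            for idx, site in enumerate(annotated):
                                if site.accession == "UNIMOD:35":
                                    del annotated[idx]
                                    break
                    if p_iii > 0 and any(a in heavy_accs for _p, a, _d in true_mods):
                        if rng.random() < p_iii:
                            injected.append(IssueClass.III_DOUBLE_LABEL.value)
                            extra = []
                            for site in annotated:
                                mapping = ptm_table.resolve(site.accession)
                                if mapping and mapping.label_role == "heavy":
                                    light = light_by_family[mapping.label_family]
                                    extra.append(
                                        ModificationSite(
                                            site.position,
                                            light.unimod_acc,
                                            light.mono_delta,
                                            ModOrigin.FIXED_ANNOTATION,
                                        )
                                    )
                            annotated.extend(extra)
                            annotated.sort(key=lambda s: (s.position, s.accession))

                annotated_charge = true_charge
                if p_iv > 0 and rng.random() < p_iv:
                    injected.append(IssueClass.IV_ZERO_CHARGE.value)
                    annotated_charge = 0
                elif p_v > 0 and rng.random() < p_v:
                    injected.append(IssueClass.V_WRONG_CHARGE.value)
                    if true_charge == 1:
                        annotated_charge = 2
                    else:
                        annotated_charge = true_charge + (
                            1 if rng.random() < 0.5 else -1
                        )

                spectra.append(
                    Spectrum(
                        spectrum_id=spectrum_id,
                        title=spectrum_id,
                        precursor_mz=float(mz),
                        precursor_charge=annotated_charge,
                        peaks=peaks,
                    )
                )
                n_prot = 1
                if (
                    config.proteins_per_peptide_max > 1
                    and rng.random() < config.multi_protein_fraction
                ):
                    n_prot = int(
                        rng.integers(2, config.proteins_per_peptide_max + 1)
                    )
                prot_idx = rng.choice(len(protein_pool), size=n_prot, replace=False)
                mappings = [
                    ProteinMapping(accession=protein_pool[int(pi)], engine=engine)
                    for pi in sorted(prot_idx)
                    for engine in engines
                ]
                scores = [
                    EngineScore(engine=e, score=round(float(rng.uniform(10, 100)), 3))
                    for e in engines
                ]
                peptides.append(
                    PeptideIdentification(
                        peptide_id=psm_id,
                        sequence=sequence,
                        spectrum_ref=spectrum_id,
                        charge_claimed=annotated_charge,
                        modifications=annotated,
                        engine_scores=scores,
                        protein_mappings=mappings,
                    )
                )
                truth.psms[(study_id, sample_id, psm_id)] = PsmTruth(
                    study_id=study_id,
                    sample_id=sample_id,
                    psm_id=psm_id,
                    sequence=sequence,
                    true_charge=true_charge,
                    annotated_charge=annotated_charge,
                    true_mods=true_mods,
                    injected=injected,
                )

            metadata = {
                key: template.format(i=s_idx + 1, n=config.psms_per_sample)
                for key, template in _METADATA_TEMPLATES.items()
            }
            samples.append(
                Sample(
                    sample_id=sample_id,
                    metadata=metadata,
                    taxa=[taxon],
                    engines=engines,
                    mgf_files=[f"{sample_id}.mgf"],
                    spectra=spectra,
                    peptides=peptides,
                )
            )
        datasets.append(
            StudyDataset(shape="source", study_id=study_id, samples=samples)
        )
    return GeneratedBatch(datasets=datasets, ground_truth=truth, config=config)


def write_batch(batch: GeneratedBatch, out_dir: str | Path) -> list[Path]:
    """Write one source XML per study, one MGF per sample, and the ground
    truth as JSON. Returns the study XML paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for dataset in batch.datasets:
        for sample in dataset.samples:
            write_mgf(sample.spectra, out_dir / sample.mgf_files[0])
        path = out_dir / f"{dataset.study_id}.xml"
        write_source_xml(dataset, path)
        paths.append(path)
    (out_dir / "ground_truth.json").write_text(
        json.dumps(batch.ground_truth.as_dicts(), indent=1), encoding="utf-8"
    )
    return paths
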