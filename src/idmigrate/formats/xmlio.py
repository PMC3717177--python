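"""Readers/writers for the source and target identification XML dialects.

Both dialects are deliberately minimal and versioned (schemas bundled as
XSD files under ``idmigrate/data/``): the migration logic, not schema
fidelity, is the point. Reading validates against the schema and reports
the offending element paths; writing is lossless for every modeled field,
including verbatim (unicode) free-text metadata. Spectra are not embedded:
samples reference MGF files, loaded separately with :func:`attach_spectra`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from lxml import etree

from idmigrate.formats.mgf import read_mgf
from idmigrate.formats.model import (
    EngineScore,
    ModOrigin,
    ModificationSite,
    PeptideIdentification,
    ProteinIdentification,
    ProteinMapping,
    Sample,
    StudyDataset,
)

__all__ = [
    "DialectValidationError",
    "read_source_xml",
    "write_source_xml",
    "read_target_xml",
    "write_target_xml",
    "attach_spectra",
]

DIALECT_VERSION = "1.0"


class DialectValidationError(ValueError):
    """Schema violation; message lists the offending element paths."""


def _load_schema(name: str) -> etree.XMLSchema:
    path = resources.files("idmigrate").joinpath(f"data/{name}")
    with resources.as_file(path) as p:
        return etree.XMLSchema(etree.parse(str(p)))


_SCHEMAS: dict[str, etree.XMLSchema] = {}


def _schema(name: str) -> etree.XMLSchema:
    if name not in _SCHEMAS:
        _SCHEMAS[name] = _load_schema(name)
    return _SCHEMAS[name]


def _validate(tree: etree._ElementTree, schema_file: str, path: str) -> None:
    schema = _schema(schema_file)
    if not schema.validate(tree):
        lines = [
            f"  {err.path or '/'}: {err.message}" for err in schema.error_log
        ]
        raise DialectValidationError(
            f"{path} does not validate against {schema_file}:\n" + "\n".join(lines)
        )


# ---------------------------------------------------------------------------
# shared element builders / parsers

def _parse_modification(el: etree._Element) -> ModificationSite:
    return ModificationSite(
        position=int(el.get("position")),
        accession=el.get("accession"),
        mono_delta=float(el.get("monoDelta")),
        origin=ModOrigin(el.get("origin")),
    )


def _mod_element(parent: etree._Element, site: ModificationSite) -> None:
    etree.SubElement(
        parent,
        "Modification",
        position=str(site.position),
        accession=site.accession,
        monoDelta=repr(site.mono_delta),
        origin=site.origin.value,
    )


def _parse_scores(el: etree._Element) -> list[EngineScore]:
    return [
        EngineScore(engine=s.get("engine"), score=float(s.get("value")))
        for s in el.findall("Score")
    ]


def _score_elements(parent: etree._Element, scores: list[EngineScore]) -> None:
    for s in scores:
        etree.SubElement(parent, "Score", engine=s.engine, value=repr(s.score))


def _parse_sample_common(el: etree._Element, sample: Sample) -> None:
    meta = el.find("Metadata")
    if meta is not None:
        for f in meta.findall("Field"):
            sample.metadata[f.get("key")] = f.text or ""
    taxa = el.find("Taxa")
    if taxa is not None:
        sample.taxa = [t.text or "" for t in taxa.findall("Taxon")]
    engines = el.find("Engines")
    if engines is not None:
        sample.engines = [e.text or "" for e in engines.findall("Engine")]
    files = el.find("SpectrumFiles")
    if files is not None:
        sample.mgf_files = [f.text or "" for f in files.findall("SpectrumFile")]


def _sample_common_elements(parent: etree._Element, sample: Sample) -> None:
    if sample.metadata:
        meta = etree.SubElement(parent, "Metadata")
        for key, value in sample.metadata.items():
            f = etree.SubElement(meta, "Field", key=key)
            f.text = value
    if sample.taxa:
        taxa = etree.SubElement(parent, "Taxa")
        for t in sample.taxa:
            etree.SubElement(taxa, "Taxon").text = t
    if sample.engines:
        engines = etree.SubElement(parent, "Engines")
        for e in sample.engines:
            etree.SubElement(engines, "Engine").text = e
    if sample.mgf_files:
        files = etree.SubElement(parent, "SpectrumFiles")
        for f in sample.mgf_files:
            etree.SubElement(files, "SpectrumFile").text = f


def _parse_peptide(el: etree._Element) -> PeptideIdentification:
    return PeptideIdentification(
        peptide_id=el.get("id"),
        sequence=el.get("sequence"),
        spectrum_ref=el.get("spectrumRef"),
        charge_claimed=int(el.get("charge")),
        modifications=[_parse_modification(m) for m in el.findall("Modification")],
        engine_scores=_parse_scores(el),
        protein_mappings=[
            ProteinMapping(accession=p.get("accession"), engine=p.get("engine"))
            for p in el.findall("ProteinMapping")
        ],
    )


def _peptide_attrs(psm: PeptideIdentification) -> dict[str, str]:
    return {
        "id": psm.peptide_id,
        "sequence": psm.sequence,
        "spectrumRef": psm.spectrum_ref,
        "charge": str(psm.charge_claimed),
    }


# ---------------------------------------------------------------------------
# source dialect

def read_source_xml(path: str | Path) -> StudyDataset:
    """Read and validate a source-dialect study file."""
    path = str(path)
    tree = etree.parse(path)
    _validate(tree, "source_dialect.xsd", path)
    root = tree.getroot()
    samples = []
    for s_el in root.findall("Sample"):
        sample = Sample(sample_id=s_el.get("id"))
        _parse_sample_common(s_el, sample)
        peptides = s_el.find("Peptides")
        if peptides is not None:
            sample.peptides = [_parse_peptide(p) for p in peptides.findall("Peptide")]
        samples.append(sample)
    return StudyDataset(shape="source", study_id=root.get("id"), samples=samples)


def write_source_xml(dataset: StudyDataset, path: str | Path) -> None:
    if dataset.shape != "source":
        raise DialectValidationError("write_source_xml requires a source-shape dataset")
    root = etree.Element(
        "SourceStudy", id=dataset.study_id, dialectVersion=DIALECT_VERSION
    )
    for sample in dataset.samples:
        s_el = etree.SubElement(root, "Sample", id=sample.sample_id)
        _sample_common_elements(s_el, sample)
        if sample.peptides:
            peps = etree.SubElement(s_el, "Peptides")
            for psm in sample.peptides:
                p_el = etree.SubElement(peps, "Peptide", **_peptide_attrs(psm))
                for site in psm.modifications:
                    _mod_element(p_el, site)
                _score_elements(p_el, psm.engine_scores)
                for m in psm.protein_mappings:
                    etree.SubElement(
                        p_el, "ProteinMapping", accession=m.accession, engine=m.engine
                    )
    tree = etree.ElementTree(root)
    _validate(tree, "source_dialect.xsd", str(path))
    tree.write(str(path), encoding="utf-8", xml_declaration=True, pretty_print=True)


# ---------------------------------------------------------------------------
# target dialect

def read_target_xml(path: str | Path) -> StudyDataset:
    """Read and validate a target-dialect project file."""
    path = str(path)
    tree = etree.parse(path)
    _validate(tree, "target_dialect.xsd", path)
    root = tree.getroot()
    samples = []
    for e_el in root.findall("Experiment"):
        sample = Sample(sample_id=e_el.get("id"))
        _parse_sample_common(e_el, sample)
        for pr_el in e_el.findall("ProteinItem"):
            protein = ProteinIdentification(
                accession=pr_el.get("accession"),
                search_engine=pr_el.get("searchEngine"),
                peptides=[_parse_peptide(p) for p in pr_el.findall("PeptideItem")],
            )
            sample.proteins.append(protein)
        samples.append(sample)
    return StudyDataset(shape="target", study_id=root.get("id"), samples=samples)


def write_target_xml(dataset: StudyDataset, path: str | Path) -> None:
    if dataset.shape != "target":
        raise DialectValidationError("write_target_xml requires a target-shape dataset")
    root = etree.Element(
        "TargetProject",
        id=dataset.study_id,
        dialectVersion=DIALECT_VERSION,
        sourceStudy=dataset.study_id,
    )
    for sample in dataset.samples:
        e_el = etree.SubElement(
            root, "Experiment", id=sample.sample_id, sourceSample=sample.sample_id
        )
        _sample_common_elements(e_el, sample)
        for protein in sample.proteins:
            pr_el = etree.SubElement(
                e_el,
                "ProteinItem",
                accession=protein.accession,
                searchEngine=protein.search_engine,
            )
            for psm in protein.peptides:
                p_el = etree.SubElement(pr_el, "PeptideItem", **_peptide_attrs(psm))
                for site in psm.modifications:
                    _mod_element(p_el, site)
                _score_elements(p_el, psm.engine_scores)
    tree = etree.ElementTree(root)
    _validate(tree, "target_dialect.xsd", str(path))
    tree.write(str(path), encoding="utf-8", xml_declaration=True, pretty_print=True)


# ---------------------------------------------------------------------------

def attach_spectra(dataset: StudyDataset, mgf_dir: str | Path) -> StudyDataset:
    """Load each sample's referenced MGF files and attach the spectra.

    Returns the same dataset (mutated) for chaining. File paths are
    interpreted relative to ``mgf_dir``.
    """
    mgf_dir = Path(mgf_dir)
    for sample in dataset.samples:
        spectra = []
        for name in sample.mgf_files:
            spectra.extend(read_mgf(mgf_dir / name))
        sample.spectra = spectra
    return dataset
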