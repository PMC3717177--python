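"""Modification vocabulary mapping.

The source data model annotates post-translational modifications with
Unimod-style accessions; the target model requires PSI-MOD-style accessions.
This module loads a flat mapping table (one record per modification type,
tab-separated, bundled but user-replaceable), resolves accessions in either
direction, and answers the one semantic question the validator needs from
the vocabulary: which modifications are the light/heavy members of the same
isotopic labelling reagent family. A quantification label incorrectly added
as a *fixed* annotation next to the *reported* form of the same reagent on
one residue is a recognised defect class, and the label registry is what
makes it detectable without any mass arithmetic.

Unmapped accessions are never silently dropped: resolution raises
:class:`UnmappedPtmError` carrying the accession, and the conversion layer
records it while carrying the modification through with its mass delta.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from idmigrate.formats import PeptideIdentification

__all__ = [
    "PtmMapping",
    "PtmTable",
    "PtmTableError",
    "UnmappedPtmError",
    "load_table",
    "load_default_table",
]

_TERMINI = {"N-term", "C-term"}


class PtmTableError(ValueError):
    """Malformed mapping table."""


class UnmappedPtmError(KeyError):
    """An accession absent from the mapping table.

    Attributes
    ----------
    accession:
        The accession that failed to resolve.
    """

    def __init__(self, accession: str):
        super().__init__(accession)
        self.accession = accession

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return f"unmapped PTM accession {self.accession!r}"


@dataclass(frozen=True)
class PtmMapping:
    """One modification type: accession pair, mass delta, specificity."""

    unimod_acc: str
    psimod_acc: str
    name: str
    composition: str
    mono_delta: float
    residue_specificity: frozenset[str]
    label_family: str | None = None
    label_role: str | None = None  # "light" | "heavy" when label_family set


class PtmTable:
    """Mapping table indexed by both accession systems."""

    def __init__(self, mappings: Iterable[PtmMapping]):
        self._by_unimod: dict[str, PtmMapping] = {}
        self._by_psimod: dict[str, PtmMapping] = {}
        for m in mappings:
            if m.unimod_acc in self._by_unimod:
                raise PtmTableError(f"duplicate unimod accession {m.unimod_acc}")
            self._by_unimod[m.unimod_acc] = m
            # psimod side may legitimately be shared; keep first occurrence
            self._by_psimod.setdefault(m.psimod_acc, m)
        self._check_label_families()

    def _check_label_families(self) -> None:
        families: dict[str, dict[str, PtmMapping]] = {}
        for m in self._by_unimod.values():
            if m.label_family:
                if m.label_role not in ("light", "heavy"):
                    raise PtmTableError(
                        f"{m.unimod_acc}: label_family {m.label_family!r} "
                        f"requires role light or heavy, got {m.label_role!r}"
                    )
                families.setdefault(m.label_family, {})[m.label_role] = m
        for fam, roles in families.items():
            if set(roles) == {"light", "heavy"}:
                if not roles["heavy"].mono_delta > roles["light"].mono_delta:
                    raise PtmTableError(
                        f"label family {fam}: heavy delta must exceed light"
                    )

    def __len__(self) -> int:
        return len(self._by_unimod)

    def __iter__(self) -> Iterator[PtmMapping]:
        return iter(self._by_unimod.values())

    def map_unimod_to_psimod(self, unimod_acc: str) -> PtmMapping:
        """Resolve a Unimod-style accession; raises :class:`UnmappedPtmError`."""
        try:
            return self._by_unimod[unimod_acc]
        except KeyError:
            raise UnmappedPtmError(unimod_acc) from None

    def resolve(self, accession: str) -> PtmMapping | None:
        """Look up an accession in either system; None when absent."""
        return self._by_unimod.get(accession) or self._by_psimod.get(accession)

    def label_mappings(self) -> list[PtmMapping]:
        return [m for m in self._by_unimod.values() if m.label_family]

    def find_label_conflicts(
        self, peptide: "PeptideIdentification"
    ) -> list[tuple[int, PtmMapping, PtmMapping]]:
        """Positions carrying >= 2 modifications from one label family.

        Returns ``(position, light_mapping, heavy_mapping)`` triples, one per
        conflicted site. Purely positional and family-local: modifications at
        other positions, or from other families, never affect the result.
        Unresolvable accessions are ignored (they carry no family).
        """
        by_pos: dict[int, dict[str, dict[str, PtmMapping]]] = {}
        for site in peptide.modifications:
            m = self.resolve(site.accession)
            if m is None or not m.label_family:
                continue
            by_pos.setdefault(site.position, {}).setdefault(m.label_family, {})[
                m.label_role or ""
            ] = m
        conflicts = []
        for pos in sorted(by_pos):
            for roles in by_pos[pos].values():
                if len(roles) >= 2:
                    conflicts.append((pos, roles["light"], roles["heavy"]))
        return conflicts


def _parse_specificity(text: str) -> frozenset[str]:
    out = set()
    for tok in text.split(","):
        tok = tok.strip()
        if not tok:
            continue
        if tok not in _TERMINI and not (len(tok) == 1 and tok.isalpha()):
            raise PtmTableError(f"bad specificity token {tok!r}")
        out.add(tok)
    return frozenset(out)


def load_table(path: str | Path) -> PtmTable:
    """Load a tab-separated mapping table (``#`` lines are comments)."""
    mappings = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 8:
            raise PtmTableError(
                f"{path}:{lineno}: expected 8 tab-separated fields, got {len(fields)}"
            )
        unimod, psimod, name, comp, delta, spec, family, role = fields
        try:
            mono_delta = float(delta)
        except ValueError:
            raise PtmTableError(f"{path}:{lineno}: bad mono_delta {delta!r}") from None
        mappings.append(
            PtmMapping(
                unimod_acc=unimod,
                psimod_acc=psimod,
                name=name,
                composition=comp,
                mono_delta=mono_delta,
                residue_specificity=_parse_specificity(spec),
                label_family=None if family == "-" else family,
                label_role=None if role == "-" else role,
            )
        )
    if not mappings:
        raise PtmTableError(f"{path}: empty mapping table")
    return PtmTable(mappings)


def default_table_path() -> Path:
    return Path(resources.files("idmigrate").joinpath("data/ptm_table.tsv"))  # type: ignore[arg-type]


def load_default_table() -> PtmTable:
    """Load the bundled curated table (a documented stand-in, replaceable)."""
    return load_table(default_table_path())
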