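"""Shared fixtures and independent oracles.

The mass oracle deliberately takes a different route from the package:
peptide and modification masses are computed from *elemental compositions*
via pyteomics (sum atoms, then sum atomic monoisotopic masses), never from
the package's residue table.
"""

from __future__ import annotations

import numpy as np
import pytest
from pyteomics import mass as pyt_mass

from idmigrate.ptm import PtmTable, load_default_table
from idmigrate.synthgen import GeneratorConfig, generate

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def elemental_peptide_mass(sequence: str, mod_deltas=()) -> float:
    """Independent oracle: elemental-composition peptide mass + deltas."""
    return pyt_mass.calculate_mass(sequence=sequence) + sum(mod_deltas)


def elemental_formula_mass(formula: str) -> float:
    """Independent oracle for a modification's elemental delta formula."""
    return pyt_mass.calculate_mass(formula=formula)


@pytest.fixture(scope="session")
def ptm_table() -> PtmTable:
    return load_default_table()


@pytest.fixture(scope="session")
def clean_batch():
    """A small defect-free, noise-free generated batch."""
    return generate(
        GeneratorConfig(seed=42, n_studies=2, samples_per_study=2, psms_per_sample=25)
    )


def random_peptides(rng: np.random.Generator, n: int, lo: int = 5, hi: int = 30):
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        yield "".join(AA20[int(i)] for i in rng.integers(0, 20, length))
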