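import numpy as np
import pytest

from sterol4d.library import LibraryEntry, SterolCompound, SterolLibrary
from sterol4d.simulate import LibrarySpec, make_library
from sterol4d.spectra import Spectrum


def make_entry(name="cholesterol", formula="C27H46O", n_oh=1, adduct="[M+H]+",
               mz=None, rt=600.0, ccs=250.0, tier="standard", spectrum=None,
               subclass="cholesterol and derivatives", **kw):
    """Convenience builder for a library entry with sane defaults."""
    from sterol4d import chem

    comp = SterolCompound(name=name, formula=formula, n_hydroxyl=n_oh, subclass=subclass)
    if mz is None:
        mz = chem.derivatized_mz(comp, adduct)
    src = "measured" if tier == "standard" else "predicted"
    return LibraryEntry(compound=comp, adduct=adduct, mz=mz, rt=rt, ccs=ccs,
                        spectrum=spectrum, tier=tier, rt_source=src, ccs_source=src, **kw)


@pytest.fixture(scope="session")
def small_libraries():
    """A compact synthetic library pair for fast matcher/separation tests."""
    return make_library(LibrarySpec(n_standard=40, n_extended=120, seed=11))


@pytest.fixture(scope="session")
def study_libraries():
    """Library pair at the study scale (97 standard, 2068 extended)."""
    return make_library(LibrarySpec(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_peak_spectrum():
    return Spectrum(np.array([100.0, 200.0]), np.array([100.0, 50.0]))
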