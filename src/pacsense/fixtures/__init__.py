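"""Packaged synthetic fixtures with recorded generator settings.

Each fixture is a delimited-text signal produced by the package's own
generators with the configuration frozen below; ``scripts/make_fixtures.py``
regenerates the files bit-exactly.  The two test signals are the smooth
compressible inputs used by the sparsity-profiling examples and tests;
the contrast set is one realization of the three-arm enhancement
experiment.
"""

from __future__ import annotations

from importlib import resources

from ..io import read_signal
from ..phantom import PhantomConfig, TestSignalConfig
from ..signals import Signal1D

#: generator settings behind the packaged test signals
TEST_SIGNAL_CONFIGS = {
    "test_signal_n1841": TestSignalConfig(
        N=1841, kind="harmonic_mixture", components=8, snr_db=25.0, seed=1
    ),
    "test_signal_n300": TestSignalConfig(
        N=300, kind="harmonic_mixture", components=4, snr_db=25.0, seed=3
    ),
}

#: settings behind the packaged three-group contrast set
CONTRAST_CONFIG = PhantomConfig()
CONTRAST_SEED = 11
CONTRAST_FACTOR = 3.0

CONTRAST_NAMES = tuple(
    f"contrast_{group.lower()}_{stage}"
    for group in ("AP_GNP", "NP", "water")
    for stage in ("pre", "post")
)


def available() -> tuple[str, ...]:
    """Names of all packaged fixtures."""
    return tuple(TEST_SIGNAL_CONFIGS) + CONTRAST_NAMES


def load_signal(name: str) -> Signal1D:
    """Load a packaged fixture signal by name (see :func:`available`)."""
    if name not in available():
        raise KeyError(f"unknown fixture {name!r}; available: {available()}")
    ref = resources.files(__package__) / f"{name}.txt"
    with resources.as_file(ref) as path:
        signal = read_signal(path)
    signal.label = name
    return signal
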