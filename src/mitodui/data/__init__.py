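"""Packaged synthetic fixture pair.

``f_like.fasta``/``m_like.fasta`` (+ ``.features.tsv``) are one frozen
realization of :func:`mitodui.simulate.solenaia_like_pair` — synthetic
stand-ins for a female-type and male-type unionoid mitogenome pair, NOT real
sequence data.  A test regenerates them from the generator and asserts they
match, so the files can never drift from the code.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from ..genome import MitoGenome, load_genome

FIXTURE_SEED = 20130848


def fixture_path(name: str) -> Path:
    return Path(str(resources.files(__package__) / name))


def solenaia_fixture_pair() -> tuple[MitoGenome, MitoGenome]:
    """Load the packaged synthetic F-like/M-like genome pair."""
    f = load_genome(fixture_path("f_like.fasta"), "fasta", sex_type="F")
    m = load_genome(fixture_path("m_like.fasta"), "fasta", sex_type="M")
    return f, m
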