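"""Access to the lexicons shipped with the package."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

from .gazetteer import Gazetteer


def _data_path(name: str) -> Path:
    return Path(resources.files("occmine").joinpath("data", name))  # type: ignore[arg-type]


@lru_cache(maxsize=None)
def default_gazetteer() -> Gazetteer:
    return Gazetteer.from_tsv(_data_path("gazetteer.tsv"))


@lru_cache(maxsize=None)
def default_healthcare_filter() -> frozenset[str]:
    from .io import read_filter_list

    return frozenset(read_filter_list(_data_path("healthcare_filter.txt")))


def _read_lines(name: str) -> tuple[str, ...]:
    out = []
    for line in _data_path(name).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return tuple(out)


@lru_cache(maxsize=None)
def kinship_terms() -> tuple[str, ...]:
    return _read_lines("kinship.txt")


@lru_cache(maxsize=None)
def surname_pool() -> tuple[str, ...]:
    return _read_lines("names.txt")


@lru_cache(maxsize=None)
def out_of_lexicon_occupations() -> tuple[str, ...]:
    return _read_lines("oov_occupations.txt")
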