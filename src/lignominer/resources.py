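"""Access to packaged data files: lexicon tables, cue lists, stoplists, schema."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import List

__all__ = ["data_path", "load_list"]


def data_path(relative: str) -> Path:
    """Filesystem path of a packaged data file (e.g. ``lexicons/enzymes.tsv``)."""
    path = Path(str(resources.files("lignominer").joinpath("data", relative)))
    if not path.exists():
        raise FileNotFoundError(f"packaged data file not found: {relative}")
    return path


@lru_cache(maxsize=None)
def _load_list_cached(relative: str) -> tuple:
    lines = data_path(relative).read_text(encoding="utf-8").splitlines()
    return tuple(
        line.strip() for line in lines if line.strip() and not line.lstrip().startswith("#")
    )


def load_list(relative_or_path) -> List[str]:
    """Load a one-entry-per-line list file; '#' lines are comments.

    Accepts a packaged-data relative name or an absolute/external path.
    """
    p = Path(str(relative_or_path))
    if p.is_absolute() or p.exists():
        lines = p.read_text(encoding="utf-8").splitlines()
        return [l.strip() for l in lines if l.strip() and not l.lstrip().startswith("#")]
    return list(_load_list_cached(str(relative_or_path)))
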