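"""Bundled small datasets.

Currently one table: literature-curated experimental R-loop present/absent
calls at 22 gene loci paired with the structural model's prediction at each
locus, used to benchmark accuracy, sensitivity and specificity.
"""

from __future__ import annotations

from importlib.resources import files


def experimental_calls_path() -> str:
    """Path to the curated (locus, experimental, predicted) call table."""
    return str(files("rlfscan") / "data" / "experimental_rloop_calls.tsv")


def experimental_calls() -> list[tuple[str, str, str]]:
    """The curated call table as (locus, 'present'/'absent', ...) rows."""
    from .annotate import read_calls_table

    return read_calls_table(experimental_calls_path())
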