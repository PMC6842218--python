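"""Column-name conventions for count tables.

A SNP count table is a wide TSV: ``site_id``, ``gene_id``, then one column
per library/allele combination named ``<class>_r<rep>_<allele>`` where
class is one of ``parent1``, ``parent2``, ``f1`` and allele is ``a1``
(the parent-1 allele) or ``a2`` (the parent-2 allele).  Parental libraries
normally carry only their own allele; a cross-allele parent column is
accepted so that parental-homozygosity violations can be detected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

SAMPLE_CLASSES = ("parent1", "parent2", "f1")
ALLELES = ("a1", "a2")
OWN_ALLELE = {"parent1": "a1", "parent2": "a2"}

_COUNT_COL = re.compile(r"^(parent1|parent2|f1)_r(\d+)_(a1|a2)$")
KEY_COLUMNS = ("site_id", "gene_id")


@dataclass(frozen=True)
class LibraryColumn:
    """One library/allele count column."""

    sample_class: str
    replicate: int
    allele: str

    @property
    def library(self) -> str:
        return f"{self.sample_class}_r{self.replicate}"

    @property
    def name(self) -> str:
        return f"{self.sample_class}_r{self.replicate}_{self.allele}"


def parse_count_column(name: str) -> LibraryColumn | None:
    """Parse a count-column name; ``None`` if it is not one."""
    m = _COUNT_COL.match(name)
    if m is None:
        return None
    return LibraryColumn(m.group(1), int(m.group(2)), m.group(3))


def count_columns(columns) -> list[LibraryColumn]:
    """Return the parsed count columns of a table, validating structure.

    Requires every F1 replicate to carry both alleles and at least one
    library per sample class to be present.
    """
    cols = [c for c in (parse_count_column(str(c)) for c in columns) if c is not None]
    if not cols:
        raise ValueError("no count columns found (expected e.g. 'parent1_r1_a1')")
    f1_alleles: dict[int, set[str]] = {}
    for c in cols:
        if c.sample_class == "f1":
            f1_alleles.setdefault(c.replicate, set()).add(c.allele)
    for rep, alleles in f1_alleles.items():
        if alleles != {"a1", "a2"}:
            raise ValueError(f"F1 replicate {rep} must carry exactly alleles a1 and a2")
    present = {c.sample_class for c in cols}
    missing = set(SAMPLE_CLASSES) - present
    if missing:
        raise ValueError(f"missing sample classes in count table: {sorted(missing)}")
    return cols


def library_class(library: str) -> str:
    """Sample class of a library id like ``f1_r2``."""
    cls = library.split("_r")[0]
    if cls not in SAMPLE_CLASSES:
        raise ValueError(f"cannot parse library id {library!r}")
    return cls
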