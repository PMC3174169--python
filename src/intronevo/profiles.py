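"""Intron presence/absence profile tables.

A profile table records, for every species (row) and every candidate
intron site (column), whether a splice site is present (``1``), absent
(``0``) or unresolvable (``*`` — missing ortholog or ambiguous alignment).
Each site carries its source gene and intron phase (0/1/2, the position
of the intron relative to codon boundaries).

Canonical on-disk dialect: tab-separated, first column ``species``,
site headers ``gene:column:phase``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: integer codes for table entries; '*' is stored as 2
ABSENT, PRESENT, AMBIGUOUS = 0, 1, 2

_CHAR_TO_CODE = {"0": ABSENT, "1": PRESENT, "*": AMBIGUOUS}
_CODE_TO_CHAR = {v: k for k, v in _CHAR_TO_CODE.items()}


class ProfileError(ValueError):
    """Raised for malformed profile-table input."""


@dataclass(frozen=True)
class Site:
    """One intron site: identifier, source gene, and phase (0, 1 or 2)."""

    site_id: str
    gene: str
    phase: int

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ProfileError(f"site {self.site_id!r}: phase must be 0/1/2, "
                               f"got {self.phase}")


@dataclass
class ProfileTable:
    """Presence/absence matrix over species × intron sites.

    ``entries`` is an int8 array of shape (n_species, n_sites) with codes
    0 (absent), 1 (present), 2 (ambiguous '*').  Species order is fixed
    and meaningful (it must match the tree's leaf set at pipeline
    assembly, in any order).
    """

    species: list[str]
    sites: list[Site]
    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.int8)
        if self.entries.shape != (len(self.species), len(self.sites)):
            raise ProfileError(
                f"entries shape {self.entries.shape} does not match "
                f"{len(self.species)} species x {len(self.sites)} sites"
            )
        if len(set(self.species)) != len(self.species):
            raise ProfileError("duplicate species name")
        if self.entries.size and not np.isin(self.entries, [0, 1, 2]).all():
            raise ProfileError("entries must be coded 0/1/2 ('*'→2)")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ProfileError("duplicate site id")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def phases(self) -> np.ndarray:
        return np.array([s.phase for s in self.sites], dtype=np.int64)

    def column(self, j: int) -> np.ndarray:
        return self.entries[:, j]

    def select_sites(self, keep: np.ndarray) -> "ProfileTable":
        keep = np.asarray(keep)
        return ProfileTable(
            species=list(self.species),
            sites=[self.sites[j] for j in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.sites[j] for j in keep],
            entries=self.entries[:, keep],
        )

    def reorder_species(self, order: list[str]) -> "ProfileTable":
        """Return a copy with rows permuted into the given species order."""
        if sorted(order) != sorted(self.species):
            raise ProfileError("species sets differ")
        idx = [self.species.index(s) for s in order]
        return ProfileTable(list(order), list(self.sites), self.entries[idx])


@dataclass(frozen=True)
class DropReport:
    """Why a column was removed by :func:`filter_columns`."""

    site_id: str
    reason: str


def read_table(path: str) -> ProfileTable:
    """Read a profile table in the canonical TSV dialect.

    First header cell must be ``species``; remaining header cells are
    ``gene:column:phase`` site identifiers.  Entries are ``0``, ``1`` or
    ``*`` only.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ProfileError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != "species":
        raise ProfileError(f"{path}: first header cell must be 'species', "
                           f"got {header[0]!r}")
    sites = []
    for tok in header[1:]:
        parts = tok.split(":")
        if len(parts) != 3:
            raise ProfileError(f"{path}: site header {tok!r} is not "
                               "gene:column:phase")
        gene, col, phase_s = parts
        try:
            phase = int(phase_s)
        except ValueError:
            raise ProfileError(f"{path}: non-integer phase in {tok!r}") from None
        if phase not in (0, 1, 2):
            raise ProfileError(f"{path}: phase must be 0/1/2 in {tok!r}")
        sites.append(Site(site_id=tok, gene=gene, phase=phase))
    species, rows = [], []
    for ln_no, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(sites) + 1:
            raise ProfileError(f"{path}:{ln_no}: expected {len(sites)+1} cells, "
                               f"got {len(cells)}")
        sp = cells[0]
        if sp in species:
            raise ProfileError(f"{path}:{ln_no}: duplicate species {sp!r}")
        species.append(sp)
        row = []
        for j, c in enumerate(cells[1:]):
            if c not in _CHAR_TO_CODE:
                raise ProfileError(
                    f"{path}:{ln_no}: bad entry {c!r} for species {sp!r}, "
                    f"site {sites[j].site_id!r} (allowed: 0 1 *)"
                )
            row.append(_CHAR_TO_CODE[c])
        rows.append(row)
    entries = np.array(rows, dtype=np.int8).reshape(len(species), len(sites))
    return ProfileTable(species=species, sites=sites, entries=entries)


def write_table(table: ProfileTable, path: str) -> None:
    """Write a table in the canonical TSV dialect (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("species\t" + "\t".join(s.site_id for s in table.sites) + "\n")
        for i, sp in enumerate(table.species):
            chars = [_CODE_TO_CHAR[int(c)] for c in table.entries[i]]
            fh.write(sp + "\t" + "\t".join(chars) + "\n")


def filter_columns(
    table: ProfileTable,
    max_ambiguous: int | None = None,
    max_ambiguous_fraction: float = 0.25,
) -> tuple[ProfileTable, list[DropReport]]:
    """Apply the observability/ambiguity column filter.

    A column is retained iff it has at least one unambiguous presence
    (``1``) and at most ``max_ambiguous`` ambiguous entries.  The default
    threshold is a fraction (0.25) of the species count, matching a cap
    of 24 ambiguous entries out of 99 species; an absolute
    ``max_ambiguous`` overrides the fraction.

    Returns the filtered table and a report of dropped columns.
    """
    if max_ambiguous is None:
        max_ambiguous = int(max_ambiguous_fraction * table.n_species)
    if max_ambiguous < 0:
        raise ProfileError("max_ambiguous must be >= 0")
    n_present = (table.entries == PRESENT).sum(axis=0)
    n_ambig = (table.entries == AMBIGUOUS).sum(axis=0)
    keep = (n_present >= 1) & (n_ambig <= max_ambiguous)
    dropped = []
    for j in np.flatnonzero(~keep):
        if n_present[j] < 1:
            reason = "no presence"
        else:
            reason = f"{n_ambig[j]} ambiguous entries > {max_ambiguous}"
        dropped.append(DropReport(site_id=table.sites[j].site_id, reason=reason))
    return table.select_sites(keep), dropped


def write_outputs(node_summary, site_surface, summary_path: str,
                  surface_path: str) -> None:
    """Write the per-node summary and per-site×node posterior tables.

    Both are tab-separated with a fixed column order (sorted rows by
    their leading key columns); identical inputs produce byte-identical
    files.  Empty inputs yield header-only files.
    """
    import pandas as pd

    def _dump(df: pd.DataFrame, path: str, keys: list[str]) -> None:
        df = df.copy()
        present = [k for k in keys if k in df.columns]
        if present and len(df):
            df = df.sort_values(present, kind="mergesort")
        df.to_csv(path, sep="\t", index=False, float_format="%.10g",
                  lineterminator="\n")

    _dump(pd.DataFrame(node_summary), summary_path, ["node", "method"])
    _dump(pd.DataFrame(site_surface), surface_path, ["site", "node"])


def check_species_match(table: ProfileTable, tree_leaf_names: list[str]) -> None:
    """Assert the table's species set equals the tree's leaf set."""
    t, l = set(table.species), set(tree_leaf_names)
    if t != l:
        missing = sorted(l - t)[:5]
        extra = sorted(t - l)[:5]
        raise ProfileError(
            f"species/tree mismatch; in tree only: {missing}, "
            f"in table only: {extra}"
        )
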