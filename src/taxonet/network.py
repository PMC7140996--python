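"""Labelled bipartite plant-pollinator networks and taxonomic aggregation.

A network is a plants x pollinators matrix of non-negative interaction
values: presence/absence (binary) or visitation counts/frequencies
(weighted).  Each taxon label can be mapped, through a :class:`TaxonomyTable`,
to its genus and family, which allows a species-level network to be
collapsed to genus- or family-level resolution by merging rows (and
columns) that share the same higher-rank name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LEVELS = ("species", "genus", "family")
#: position of each level in the species -> genus -> family coarsening chain
_LEVEL_ORDER = {lvl: i for i, lvl in enumerate(LEVELS)}


class NetworkError(ValueError):
    """Raised when a network or taxonomy violates its invariants."""


@dataclass(frozen=True)
class BipartiteNetwork:
    """A labelled plants x pollinators interaction matrix.

    Parameters
    ----------
    matrix
        Non-negative 2-D array; rows are plants, columns are pollinators.
        A binary network (``weighted=False``) may only contain 0 and 1.
    row_labels, col_labels
        Unique taxon names for plants and pollinators.
    weighted
        True for count/frequency data, False for presence/absence.
    level
        Taxonomic resolution of the labels: "species", "genus" or "family".
    name
        Free-text identifier used in output tables.
    """

    matrix: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    weighted: bool = False
    level: str = "species"
    name: str = "network"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] < 1:
            raise NetworkError("matrix must be 2-D with at least one row and column")
        if not np.all(np.isfinite(m)):
            raise NetworkError("matrix contains non-finite values")
        if (m < 0).any():
            raise NetworkError("matrix contains negative entries")
        if not m.any():
            raise NetworkError("matrix has no nonzero entry")
        if not self.weighted and not np.isin(m, (0.0, 1.0)).all():
            raise NetworkError("binary network may only contain 0/1 entries")
        if self.level not in LEVELS:
            raise NetworkError(f"unknown level {self.level!r}")
        rows = tuple(str(x) for x in self.row_labels)
        cols = tuple(str(x) for x in self.col_labels)
        if len(rows) != m.shape[0] or len(cols) != m.shape[1]:
            raise NetworkError("label count does not match matrix shape")
        if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
            raise NetworkError("duplicate taxon labels within a guild")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "row_labels", rows)
        object.__setattr__(self, "col_labels", cols)

    @property
    def n_plants(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pollinators(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.row_labels), columns=list(self.col_labels)
        )


@dataclass(frozen=True)
class TaxonRecord:
    genus: str | None = None
    family: str | None = None
    species_resolved: bool = False

    def __post_init__(self) -> None:
        if self.species_resolved and (self.genus is None or self.family is None):
            raise NetworkError(
                "species_resolved taxa must carry both genus and family"
            )


@dataclass(frozen=True)
class TaxonomyTable:
    """Per-guild mapping from taxon label to (genus, family).

    Within a guild every genus must belong to exactly one family.
    """

    plants: Mapping[str, TaxonRecord] = field(default_factory=dict)
    pollinators: Mapping[str, TaxonRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        genus_maps = []
        for guild in (self.plants, self.pollinators):
            genus_family: dict[str, str] = {}
            for label, rec in guild.items():
                if rec.genus is None or rec.family is None:
                    continue
                known = genus_family.setdefault(rec.genus, rec.family)
                if known != rec.family:
                    raise NetworkError(
                        f"genus {rec.genus!r} maps to families "
                        f"{known!r} and {rec.family!r}"
                    )
            genus_maps.append(genus_family)
        object.__setattr__(self, "_genus_family", tuple(genus_maps))

    def guild(self, side: str) -> Mapping[str, TaxonRecord]:
        return self.plants if side == "plant" else self.pollinators

    def parent(self, side: str, label: str, level: str) -> str | None:
        rec = self.guild(side).get(label)
        if rec is not None:
            return rec.genus if level == "genus" else rec.family
        if level == "family":
            # the label may itself be a genus name (genus-level network)
            gmap = self._genus_family[0 if side == "plant" else 1]
            return gmap.get(label)
        return None


def binarize(net: BipartiteNetwork) -> BipartiteNetwork:
    """Map every positive entry to 1 and flag the result as binary."""
    if not net.weighted:
        return net
    return replace(net, matrix=(net.matrix > 0).astype(float), weighted=False)


def _drop_empty(matrix: np.ndarray, rows: Iterable[str], cols: Iterable[str]):
    keep_r = matrix.any(axis=1)
    keep_c = matrix.any(axis=0)
    sub = matrix[np.ix_(keep_r, keep_c)]
    return (
        sub,
        [l for l, k in zip(rows, keep_r) if k],
        [l for l, k in zip(cols, keep_c) if k],
    )


def filter_species_resolved(
    net: BipartiteNetwork, tax: TaxonomyTable
) -> BipartiteNetwork:
    """Keep only interactions whose plant AND pollinator are resolved to species.

    Unresolved rows/columns are removed, then rows or columns left with no
    interactions are dropped as well.  Label order is preserved.
    """
    if net.level != "species":
        raise NetworkError("species filtering applies to species-level networks")
    for side, labels in (("plant", net.row_labels), ("pollinator", net.col_labels)):
        missing = [l for l in labels if l not in tax.guild(side)]
        if missing:
            raise NetworkError(f"taxa absent from taxonomy: {missing}")
    keep_r = np.array(
        [tax.plants[l].species_resolved for l in net.row_labels], dtype=bool
    )
    keep_c = np.array(
        [tax.pollinators[l].species_resolved for l in net.col_labels], dtype=bool
    )
    sub = net.matrix[np.ix_(keep_r, keep_c)]
    rows = [l for l, k in zip(net.row_labels, keep_r) if k]
    cols = [l for l, k in zip(net.col_labels, keep_c) if k]
    if sub.size == 0 or not sub.any():
        raise NetworkError("no species-resolved interactions")
    sub, rows, cols = _drop_empty(sub, rows, cols)
    return replace(
        net, matrix=sub, row_labels=tuple(rows), col_labels=tuple(cols)
    )


def _group_indices(labels, parents):
    """First-appearance-ordered grouping of labels by their parent name."""
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, p in enumerate(parents):
        if p not in groups:
            groups[p] = []
            order.append(p)
        groups[p].append(i)
    return order, groups


def aggregate(
    net: BipartiteNetwork, tax: TaxonomyTable, target_level: str
) -> BipartiteNetwork:
    """Collapse a network to genus or family resolution.

    Rows (and columns) whose taxa share the same target-level name are
    merged: entrywise sum for weighted matrices (visitation counts are
    additive), entrywise logical OR for binary ones.  Output labels are the
    target-level names in order of first appearance.
    """
    if target_level not in LEVELS:
        raise NetworkError(f"unknown level {target_level!r}")
    if _LEVEL_ORDER[target_level] <= _LEVEL_ORDER[net.level]:
        raise NetworkError(
            f"target level {target_level!r} is not coarser than {net.level!r}"
        )

    parents = {}
    for side, labels in (("plant", net.row_labels), ("pollinator", net.col_labels)):
        ps = []
        for l in labels:
            p = tax.parent(side, l, target_level)
            if p is None:
                raise NetworkError(
                    f"{side} taxon {l!r} has no {target_level} in the taxonomy"
                )
            ps.append(p)
        parents[side] = ps

    row_names, row_groups = _group_indices(net.row_labels, parents["plant"])
    col_names, col_groups = _group_indices(net.col_labels, parents["pollinator"])
    out = np.zeros((len(row_names), len(col_names)))
    for i, rn in enumerate(row_names):
        block = net.matrix[row_groups[rn], :]
        for j, cn in enumerate(col_names):
            cell = block[:, col_groups[cn]]
            out[i, j] = cell.sum() if net.weighted else float(cell.any())
    return replace(
        net,
        matrix=out,
        row_labels=tuple(row_names),
        col_labels=tuple(col_names),
        level=target_level,
    )


def check_multifamily(
    net: BipartiteNetwork, tax: TaxonomyTable, min_families: int = 2
) -> bool:
    """True iff each guild spans at least ``min_families`` distinct families."""
    for side, labels in (("plant", net.row_labels), ("pollinator", net.col_labels)):
        fams = {
            tax.guild(side)[l].family
            for l in labels
            if l in tax.guild(side) and tax.guild(side)[l].family is not None
        }
        if len(fams) < min_families:
            return False
    return True


# ---------------------------------------------------------------------------
# delimited-text I/O

def read_matrix(path, name: str | None = None, weighted: bool | None = None,
                level: str = "species") -> BipartiteNetwork:
    """Read a network from delimited text.

    First row holds pollinator labels, first column plant labels.  The
    delimiter is sniffed between comma and tab.  If ``weighted`` is None the
    matrix is treated as binary when every entry is 0 or 1.
    """
    df = pd.read_csv(path, index_col=0, sep=None, engine="python")
    m = df.to_numpy(dtype=float)
    if weighted is None:
        weighted = not np.isin(m, (0.0, 1.0)).all()
    return BipartiteNetwork(
        matrix=m,
        row_labels=tuple(str(x) for x in df.index),
        col_labels=tuple(str(x) for x in df.columns),
        weighted=weighted,
        level=level,
        name=name if name is not None else str(path),
    )


def write_matrix(net: BipartiteNetwork, path) -> None:
    net.to_frame().to_csv(path)


def read_taxonomy(path) -> TaxonomyTable:
    """Read a taxonomy table with columns guild, taxon, species_resolved, genus, family."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"guild", "taxon", "species_resolved", "genus", "family"}
    if not required.issubset(df.columns):
        raise NetworkError(f"taxonomy file must have columns {sorted(required)}")
    guilds: dict[str, dict[str, TaxonRecord]] = {"plant": {}, "pollinator": {}}
    for _, row in df.iterrows():
        guild = str(row["guild"]).strip().lower()
        if guild not in guilds:
            raise NetworkError(f"unknown guild {row['guild']!r}")
        resolved = str(row["species_resolved"]).strip().lower() in (
            "1", "true", "yes",
        )
        genus = None if pd.isna(row["genus"]) else str(row["genus"])
        family = None if pd.isna(row["family"]) else str(row["family"])
        guilds[guild][str(row["taxon"])] = TaxonRecord(
            genus=genus, family=family, species_resolved=resolved
        )
    return TaxonomyTable(plants=guilds["plant"], pollinators=guilds["pollinator"])


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    rows = []
    for guild, mapping in (("plant", tax.plants), ("pollinator", tax.pollinators)):
        for label, rec in mapping.items():
            rows.append(
                {
                    "guild": guild,
                    "taxon": label,
                    "species_resolved": rec.species_resolved,
                    "genus": rec.genus,
                    "family": rec.family,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
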