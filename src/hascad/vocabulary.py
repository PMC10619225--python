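"""The 15-type immune cell vocabulary shared by every composition vector.

The fixed order below defines the index of every fraction vector produced
or consumed by the package: simulated ground truths, network outputs and
evaluation reports all use it. The types cover two dendritic subsets, two
B subsets, three CD4 T subsets (incl. regulatory T), three CD8 T subsets,
haematopoietic stem cells, megakaryocytes, two monocyte subsets and NK
cells -- the immune populations resolvable in PBMC single-cell references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["CellTypeVocabulary", "DEFAULT_VOCABULARY", "CELL_TYPES"]

CELL_TYPES: tuple[str, ...] = (
    "aDC",
    "pDC",
    "bmem",
    "bnaive",
    "cd4mem",
    "cd4naive",
    "treg",
    "cd8eff",
    "cd8mem",
    "cd8naive",
    "hsc",
    "mk",
    "mono14",
    "mono16",
    "nk",
)


@dataclass(frozen=True)
class CellTypeVocabulary:
    """Ordered, unique list of exactly 15 cell-type identifiers."""

    names: tuple[str, ...] = field(default=CELL_TYPES)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) != 15:
            raise ValueError(f"vocabulary must have exactly 15 entries, got {len(names)}")
        if len(set(names)) != len(names):
            raise ValueError("vocabulary entries must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __getitem__(self, i: int) -> str:
        return self.names[i]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown cell type {name!r}") from None

    def __contains__(self, name: object) -> bool:
        return name in self.names


DEFAULT_VOCABULARY = CellTypeVocabulary()
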