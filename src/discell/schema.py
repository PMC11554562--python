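"""Attribute schemas: the declared structure of per-cell annotations.

A known attribute of cellular identity is either *categorical* (an unordered
class set — cell type, infection status, spatial zone) represented by a
learned embedding table, or *ordered* (a fixed-dimension numeric feature
vector — dosage, a precomputed perturbation embedding) represented through a
learned encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

__all__ = ["Attribute", "AttributeSchema", "CATEGORICAL", "ORDERED", "MISSING"]

CATEGORICAL = "categorical"
ORDERED = "ordered"

#: Reserved sentinel for a missing categorical label.  Distinct from any
#: category string a schema may declare; numeric missing values are all-NaN.
MISSING = "__missing__"


@dataclass(frozen=True)
class Attribute:
    name: str
    kind: str  # CATEGORICAL or ORDERED
    categories: Optional[tuple] = None  # categorical only, schema order fixed
    dim: Optional[int] = None  # ordered only

    def __post_init__(self):
        if self.kind not in (CATEGORICAL, ORDERED):
            raise ValueError(f"attribute {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == CATEGORICAL:
            if not self.categories:
                raise ValueError(f"categorical attribute {self.name!r} needs >= 1 category")
            if MISSING in self.categories:
                raise ValueError(f"{MISSING!r} is reserved and cannot be a category")
            if len(set(self.categories)) != len(self.categories):
                raise ValueError(f"attribute {self.name!r}: duplicate categories")
            object.__setattr__(self, "categories", tuple(self.categories))
        else:
            if self.dim is None or self.dim < 1:
                raise ValueError(f"ordered attribute {self.name!r} needs dim >= 1")

    @property
    def n_categories(self) -> int:
        if self.kind != CATEGORICAL:
            raise ValueError(f"attribute {self.name!r} is not categorical")
        return len(self.categories)

    def category_index(self, label: str) -> int:
        try:
            return self.categories.index(label)
        except ValueError:
            raise KeyError(
                f"attribute {self.name!r}: label {label!r} not in categories "
                f"{list(self.categories)}"
            ) from None


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered collection of known attributes (K may be zero)."""

    attributes: tuple = field(default_factory=tuple)

    def __post_init__(self):
        attrs = tuple(self.attributes)
        names = [a.name for a in attrs]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate attribute names: {names}")
        object.__setattr__(self, "attributes", attrs)

    @classmethod
    def from_dict(cls, spec: Dict) -> "AttributeSchema":
        """Build a schema from a plain mapping, e.g. parsed YAML/JSON.

        ``{"cell_type": {"kind": "categorical", "categories": [...]},
           "dose": {"kind": "ordered", "dim": 1}}``
        """
        attrs = []
        for name, cfg in spec.items():
            kind = cfg["kind"]
            if kind == CATEGORICAL:
                attrs.append(Attribute(name, kind, categories=tuple(cfg["categories"])))
            else:
                attrs.append(Attribute(name, kind, dim=int(cfg["dim"])))
        return cls(tuple(attrs))

    def to_dict(self) -> Dict:
        out = {}
        for a in self.attributes:
            if a.kind == CATEGORICAL:
                out[a.name] = {"kind": a.kind, "categories": list(a.categories)}
            else:
                out[a.name] = {"kind": a.kind, "dim": a.dim}
        return out

    @property
    def names(self) -> List[str]:
        return [a.name for a in self.attributes]

    @property
    def K(self) -> int:
        return len(self.attributes)

    def __len__(self) -> int:
        return len(self.attributes)

    def __iter__(self):
        return iter(self.attributes)

    def __getitem__(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(f"no attribute named {name!r}; schema has {self.names}")

    def __contains__(self, name: str) -> bool:
        return any(a.name == name for a in self.attributes)
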