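"""Item catalog: symptom items, instrument membership, and community labels.

The default catalog describes the 33 network nodes used throughout the
package: 15 child PTSD symptom scale (CPSS) items and 18 child depression
scale (CES-DC) items, of which 4 are reverse-scored positive-affect items.
Six PTSD items form the "dysphoria" set (negative mood / somatic distress
shared with depression) and are the designated candidate bridge symptoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["ItemCatalog", "default_catalog", "DYSPHORIA_ITEMS"]

#: PTSD items hypothesised to bridge into depression (dysphoria set).
DYSPHORIA_ITEMS = frozenset({"C1", "C2", "C4", "C5", "C6", "D5"})

_INSTRUMENTS = ("PTSD", "DEP")
_COMMUNITIES = ("PTSD", "DEP-NEG", "DEP-POS")

# (item_id, label, instrument, community)
_DEFAULT_ITEMS = [
    ("B1", "traumatic dreams", "PTSD", "PTSD"),
    ("B2", "intrusive memories, thoughts, or images of the trauma", "PTSD", "PTSD"),
    ("B3", "upset at reminders of the trauma", "PTSD", "PTSD"),
    ("B4", "flashbacks", "PTSD", "PTSD"),
    ("B5", "physiological reactivity", "PTSD", "PTSD"),
    ("C1", "loss of interest", "PTSD", "PTSD"),
    ("C2", "future foreshortening", "PTSD", "PTSD"),
    ("C3", "avoid activities reminiscent of the trauma", "PTSD", "PTSD"),
    ("C4", "emotionally numb", "PTSD", "PTSD"),
    ("C5", "difficulty remembering important aspects of the trauma", "PTSD", "PTSD"),
    ("C6", "feeling distant or cut off from others", "PTSD", "PTSD"),
    ("C7", "avoid thoughts and feelings about the trauma", "PTSD", "PTSD"),
    ("D3", "exaggerated startle", "PTSD", "PTSD"),
    ("D4", "hypervigilant", "PTSD", "PTSD"),
    ("D5", "irritable behavior", "PTSD", "PTSD"),
    ("A1", "bothered by things that usually do not bother me", "DEP", "DEP-NEG"),
    ("A2", "did not feel like eating", "DEP", "DEP-NEG"),
    ("A3", "could not shake off the blues", "DEP", "DEP-NEG"),
    ("A6", "felt depressed", "DEP", "DEP-NEG"),
    ("A7", "too tired to do anything", "DEP", "DEP-NEG"),
    ("A9", "feeling that everything I did was useless", "DEP", "DEP-NEG"),
    ("A10", "felt fearful", "DEP", "DEP-NEG"),
    ("A13", "talked less than usual", "DEP", "DEP-NEG"),
    ("A14", "felt lonely", "DEP", "DEP-NEG"),
    ("A15", "people were unfriendly", "DEP", "DEP-NEG"),
    ("A17", "had crying spells", "DEP", "DEP-NEG"),
    ("A18", "felt sad", "DEP", "DEP-NEG"),
    ("A19", "felt that people dislike me", "DEP", "DEP-NEG"),
    ("A20", "could not get going", "DEP", "DEP-NEG"),
    ("A4", "good as other kids", "DEP", "DEP-POS"),
    ("A8", "something good going to happen", "DEP", "DEP-POS"),
    ("A12", "was happy", "DEP", "DEP-POS"),
    ("A16", "had a good time", "DEP", "DEP-POS"),
]

#: Full published instrument lengths; the default catalog is a truncation
#: (15 of 17 CPSS items, 18 of 20 CES-DC items enter the network).
FULL_INSTRUMENT_SIZES = {"PTSD": 17, "DEP": 20}


@dataclass(frozen=True)
class ItemCatalog:
    """Catalog of symptom items with instrument and community membership.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per item with columns ``item_id``, ``label``, ``instrument``
        (``PTSD`` or ``DEP``), ``community`` (``PTSD``, ``DEP-NEG`` or
        ``DEP-POS``), ``dysphoria`` and ``reverse_scored`` (booleans).
    full_instrument_sizes : dict
        Published item counts of the full instruments; instruments whose
        catalog item count falls short are flagged as truncated in
        screening reports.
    """

    table: pd.DataFrame
    full_instrument_sizes: dict = field(default_factory=lambda: dict(FULL_INSTRUMENT_SIZES))

    def __post_init__(self) -> None:
        t = self.table
        required = {"item_id", "label", "instrument", "community", "dysphoria", "reverse_scored"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"catalog table missing columns: {sorted(missing)}")
        if t["item_id"].duplicated().any():
            dupes = t.loc[t["item_id"].duplicated(), "item_id"].tolist()
            raise ValueError(f"duplicate item ids: {dupes}")
        bad_instr = set(t["instrument"]) - set(_INSTRUMENTS)
        if bad_instr:
            raise ValueError(f"unknown instruments: {sorted(bad_instr)}")
        bad_comm = set(t["community"]) - set(_COMMUNITIES)
        if bad_comm:
            raise ValueError(f"unknown communities: {sorted(bad_comm)}")
        bad_rev = t[t["reverse_scored"] & (t["community"] != "DEP-POS")]
        if len(bad_rev):
            raise ValueError(
                "reverse_scored is only allowed for DEP-POS items; offending: "
                f"{bad_rev['item_id'].tolist()}"
            )
        object.__setattr__(self, "table", t.reset_index(drop=True))

    # -- basic access -----------------------------------------------------
    @property
    def item_ids(self) -> list[str]:
        return self.table["item_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, item_id: str) -> bool:
        return item_id in set(self.table["item_id"])

    def items_of(self, instrument: str) -> list[str]:
        if instrument not in _INSTRUMENTS:
            raise ValueError(f"unknown instrument {instrument!r}; expected one of {_INSTRUMENTS}")
        return self.table.loc[self.table["instrument"] == instrument, "item_id"].tolist()

    def community_of(self, item_id: str) -> str:
        row = self.table[self.table["item_id"] == item_id]
        if row.empty:
            raise KeyError(f"unknown item {item_id!r}")
        return row["community"].iloc[0]

    def bridging_community(self, item_id: str) -> str:
        """Two-disorder community used for bridge metrics (DEP-NEG and
        DEP-POS both collapse to ``DEP``)."""
        c = self.community_of(item_id)
        return "PTSD" if c == "PTSD" else "DEP"

    def bridging_communities(self) -> dict[str, str]:
        return {i: self.bridging_community(i) for i in self.item_ids}

    @property
    def dysphoria_items(self) -> list[str]:
        return self.table.loc[self.table["dysphoria"], "item_id"].tolist()

    @property
    def reverse_items(self) -> list[str]:
        return self.table.loc[self.table["reverse_scored"], "item_id"].tolist()

    def is_truncated(self, instrument: str) -> bool:
        full = self.full_instrument_sizes.get(instrument)
        return full is not None and len(self.items_of(instrument)) < full

    def subset(self, item_ids: Sequence[str]) -> "ItemCatalog":
        keep = self.table[self.table["item_id"].isin(item_ids)]
        order = {i: k for k, i in enumerate(item_ids)}
        keep = keep.sort_values("item_id", key=lambda s: s.map(order))
        return ItemCatalog(keep.reset_index(drop=True), dict(self.full_instrument_sizes))

    # -- serialization ----------------------------------------------------
    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ItemCatalog":
        t = pd.read_csv(path)
        t["dysphoria"] = t["dysphoria"].astype(bool)
        t["reverse_scored"] = t["reverse_scored"].astype(bool)
        return cls(t)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.table.to_dict(orient="records"), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ItemCatalog":
        with open(path) as fh:
            records = json.load(fh)
        return cls(pd.DataFrame.from_records(records))


def default_catalog(items: Iterable[str] | None = None) -> ItemCatalog:
    """Build the default 33-item catalog (or a subset of it, in the given
    order) with dysphoria and reverse-scoring flags."""
    rows = []
    for item_id, label, instrument, community in _DEFAULT_ITEMS:
        rows.append(
            {
                "item_id": item_id,
                "label": label,
                "instrument": instrument,
                "community": community,
                "dysphoria": item_id in DYSPHORIA_ITEMS,
                "reverse_scored": community == "DEP-POS",
            }
        )
    cat = ItemCatalog(pd.DataFrame.from_records(rows))
    if items is not None:
        cat = cat.subset(list(items))
    return cat
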