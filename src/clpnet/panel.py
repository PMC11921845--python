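"""Two-wave ordinal panel container, CSV I/O, total scores, and screening.

A :class:`PanelDataset` holds subject x item x wave ordinal scores (0-3,
``nan`` = missing). The wide CSV layout has one row per subject and columns
``<item>_T1`` / ``<item>_T2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import ItemCatalog

__all__ = [
    "PanelDataset",
    "SchemaError",
    "ValidationError",
    "load_panel",
    "save_panel",
    "total_score",
    "screen_prevalence",
    "DEFAULT_CUTOFFS",
]

#: Published screening cut-offs (total score >= cutoff flags positive).
DEFAULT_CUTOFFS = {"PTSD": 11, "DEP": 15}


class SchemaError(ValueError):
    """A required column is absent from an input file."""


class ValidationError(ValueError):
    """A cell value violates the ordinal 0-3 range."""


@dataclass
class PanelDataset:
    """Subjects x items x 2 waves of ordinal symptom scores.

    ``scores`` is a float array of shape (n_subjects, n_items, 2) with
    values in {0, 1, 2, 3} and ``nan`` marking missing cells.
    """

    subjects: list
    items: list
    scores: np.ndarray
    wave_labels: tuple = ("T1", "T2")
    catalog: ItemCatalog | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.subjects), len(self.items), 2):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match "
                f"({len(self.subjects)}, {len(self.items)}, 2)"
            )
        obs = self.scores[~np.isnan(self.scores)]
        if obs.size and not np.isin(obs, [0.0, 1.0, 2.0, 3.0]).all():
            bad = obs[~np.isin(obs, [0.0, 1.0, 2.0, 3.0])]
            raise ValidationError(f"scores outside {{0,1,2,3}}: e.g. {bad[:5].tolist()}")

    # -- basic properties -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_items(self) -> int:
        return len(self.items)

    def wave(self, wave) -> np.ndarray:
        """Return the (n, p) matrix of one wave ('T1'/'T2' or 0/1)."""
        return self.scores[:, :, self._wave_index(wave)]

    def _wave_index(self, wave) -> int:
        if wave in (0, 1):
            return int(wave)
        if wave in self.wave_labels:
            return self.wave_labels.index(wave)
        raise ValueError(f"unknown wave {wave!r}")

    def missing_fraction(self, wave=None) -> float:
        """Fraction of missing cells, per wave or overall."""
        a = self.scores if wave is None else self.wave(wave)
        return float(np.isnan(a).mean())

    def missing_count(self) -> int:
        return int(np.isnan(self.scores).sum())

    def is_complete(self) -> bool:
        return not np.isnan(self.scores).any()

    def item_index(self, item: str) -> int:
        try:
            return self.items.index(item)
        except ValueError:
            raise KeyError(f"unknown item {item!r}") from None


def load_panel(path, catalog: ItemCatalog) -> PanelDataset:
    """Load a wide-format CSV panel validated against ``catalog``.

    Expected columns: optional ``subject`` plus ``<item>_T1`` and
    ``<item>_T2`` for every catalog item. Empty cells become missing.

    Raises
    ------
    SchemaError
        If a required item/wave column is absent.
    ValidationError
        If any cell lies outside {0, 1, 2, 3} (reported with row and column).
    """
    df = pd.read_csv(path)
    items = catalog.item_ids
    for item in items:
        for wave in ("T1", "T2"):
            if f"{item}_{wave}" not in df.columns:
                raise SchemaError(f"missing column {item}_{wave!s}")
    if "subject" in df.columns:
        subjects = df["subject"].astype(str).tolist()
    else:
        subjects = [str(i) for i in range(len(df))]
    scores = np.full((len(df), len(items), 2), np.nan)
    for j, item in enumerate(items):
        for w, wave in enumerate(("T1", "T2")):
            col = f"{item}_{wave}"
            vals = pd.to_numeric(df[col], errors="coerce")
            raw_missing = df[col].isna()
            unparseable = vals.isna() & ~raw_missing
            if unparseable.any():
                row = int(np.flatnonzero(unparseable)[0])
                raise ValidationError(f"non-numeric value in column {col}, row {row}")
            arr = vals.to_numpy(dtype=float)
            obs = ~np.isnan(arr)
            bad = obs & ~np.isin(arr, [0.0, 1.0, 2.0, 3.0])
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"value {arr[row]:g} outside {{0..3}} in column {col}, row {row}"
                )
            scores[:, j, w] = arr
    return PanelDataset(subjects, list(items), scores, catalog=catalog)


def save_panel(ds: PanelDataset, path) -> None:
    """Write a panel back to the wide CSV layout (missing -> empty cell)."""
    data = {"subject": ds.subjects}
    for w, wave in enumerate(ds.wave_labels):
        for j, item in enumerate(ds.items):
            col = ds.scores[:, j, w]
            data[f"{item}_{wave}"] = [("" if np.isnan(v) else int(v)) for v in col]
    pd.DataFrame(data).to_csv(path, index=False)


def total_score(ds: PanelDataset, instrument: str, wave) -> np.ndarray:
    """Per-subject instrument total at one wave.

    Reverse-scored items are recoded as ``3 - x`` before summing. Subjects
    with any missing item on the instrument get a missing (nan) total —
    no proration.
    """
    catalog = ds.catalog
    if catalog is None:
        raise ValueError("dataset has no catalog attached")
    items = catalog.items_of(instrument)
    idx = [ds.item_index(i) for i in items]
    mat = ds.wave(wave)[:, idx].copy()
    rev = [k for k, i in enumerate(items) if i in set(catalog.reverse_items)]
    mat[:, rev] = 3.0 - mat[:, rev]
    return mat.sum(axis=1)  # nan propagates: any missing item -> missing total


def screen_prevalence(ds: PanelDataset, cutoffs: dict | None = None) -> pd.DataFrame:
    """Per-wave fraction of subjects at or above each instrument cut-off.

    Subjects with missing totals are excluded from the denominator. The
    returned frame flags instruments whose catalog is a truncation of the
    published scale (totals are then not comparable to published norms).
    """
    cutoffs = dict(DEFAULT_CUTOFFS if cutoffs is None else cutoffs)
    rows = []
    for instrument, cutoff in cutoffs.items():
        for wave in ds.wave_labels:
            totals = total_score(ds, instrument, wave)
            ok = ~np.isnan(totals)
            if not ok.any():
                raise ValueError(
                    f"no computable {instrument} totals at {wave}: all subjects have missing items"
                )
            prevalence = float((totals[ok] >= cutoff).mean())
            rows.append(
                {
                    "instrument": instrument,
                    "wave": wave,
                    "cutoff": cutoff,
                    "n_scored": int(ok.sum()),
                    "prevalence": prevalence,
                    "truncated_instrument": ds.catalog.is_truncated(instrument),
                }
            )
    return pd.DataFrame(rows)
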