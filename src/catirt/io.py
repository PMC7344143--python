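"""Data containers and file formats.

Response matrices are CSV/TSV files with a header row of item ids and
integer category cells; "NA" (or an empty cell) marks a missing response.
Categories are 0-based internally; 1-based files can be ingested with
``one_based=True``.  Item banks round-trip through a fixed CSV schema
(`item_id,model,a,b1,b2,b3,b4,...`) and an equivalent JSON document.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import DEFAULT_D, ItemBank, ItemParameters, ResponseDataError

MISSING = -1


@dataclass
class ResponseMatrix:
    """Persons x items integer response categories with a missing mask.

    `data` stores categories 0..K-1 with -1 at missing cells; `mask` is True
    where a response was observed.
    """

    data: np.ndarray
    item_ids: list[str]
    person_ids: list[str] | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValueError("response data must be 2-D (persons x items)")
        if data.shape[1] != len(self.item_ids):
            raise ValueError("item_ids must match the number of columns")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("duplicate item ids in response matrix")
        self.data = data.astype(np.int64)
        self.item_ids = [str(i) for i in self.item_ids]
        if self.person_ids is None:
            self.person_ids = [str(i) for i in range(data.shape[0])]

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    @property
    def mask(self) -> np.ndarray:
        return self.data != MISSING

    def column(self, item_id: str) -> np.ndarray:
        return self.data[:, self.item_ids.index(item_id)]

    def subset_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        idx = [self.item_ids.index(i) for i in item_ids]
        return ResponseMatrix(self.data[:, idx], list(item_ids), list(self.person_ids))

    def observed_categories(self, j: int) -> np.ndarray:
        col = self.data[:, j]
        return np.unique(col[col != MISSING])

    def validate_against(self, bank: ItemBank) -> None:
        """Raise if any observed category exceeds its item's K - 1."""
        for item_id in self.item_ids:
            if item_id not in bank.item_ids:
                continue
            item = bank.get(item_id)
            cats = self.observed_categories(self.item_ids.index(item_id))
            if cats.size and (cats.min() < 0 or cats.max() >= item.n_categories):
                raise ResponseDataError(
                    f"item {item_id}: observed categories {cats.tolist()} exceed "
                    f"0..{item.n_categories - 1}"
                )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data.astype(float), columns=self.item_ids)
        df[self.data == MISSING] = np.nan
        df.index = pd.Index(self.person_ids, name="person_id")
        return df


def read_response_matrix(
    path: str | Path, one_based: bool = False, bank: ItemBank | None = None
) -> ResponseMatrix:
    """Read a person x item response CSV/TSV.

    The delimiter is sniffed from the extension (.tsv -> tab).  Cells must
    be integers or the missing token "NA"/empty.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path) as fh:
        header = fh.readline().strip().split(sep)
    if len(set(header)) != len(header):  # pandas would silently rename these
        raise ValueError(f"{path}: duplicate item ids in header")
    df = pd.read_csv(path, sep=sep, na_values=["NA"], dtype=str)
    person_ids = None
    if df.columns[0].lower() in ("person_id", "person", "id"):
        person_ids = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
    item_ids = [str(c) for c in df.columns]
    if len(set(item_ids)) != len(item_ids):
        raise ValueError(f"{path}: duplicate item ids in header")
    data = np.full(df.shape, MISSING, dtype=np.int64)
    for j, col in enumerate(df.columns):
        cells = df[col]
        obs = cells.notna().to_numpy()
        try:
            vals = cells[obs].astype(float).to_numpy()
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell in column {col!r}: {exc}") from None
        if np.any(vals != np.round(vals)):
            i = int(np.where(vals != np.round(vals))[0][0])
            raise ValueError(f"{path}: non-integer cell in column {col!r}, row {i}")
        data[obs, j] = vals.astype(np.int64) - (1 if one_based else 0)
    rm = ResponseMatrix(data, item_ids, person_ids)
    if bank is not None:
        rm.validate_against(bank)
    return rm


def write_response_matrix(rm: ResponseMatrix, path: str | Path) -> None:
    df = rm.to_frame()
    df.to_csv(path, na_rep="NA", float_format="%.0f")


# ---------------------------------------------------------------------------
# Item bank serialisation

_BANK_COLUMNS = ("item_id", "model", "a")


def bank_to_frame(bank: ItemBank) -> pd.DataFrame:
    max_k = max(it.n_categories for it in bank)
    rows = []
    for it in bank:
        row = {"item_id": it.item_id, "model": it.model, "a": it.a}
        for t in range(max_k - 1):
            row[f"b{t + 1}"] = it.b[t] if t < len(it.b) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_bank(bank: ItemBank, path: str | Path) -> None:
    """Write a bank as CSV or JSON depending on the extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "D": bank.D,
            "items": [
                {"item_id": it.item_id, "model": it.model, "a": it.a, "b": list(it.b)}
                for it in bank
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    else:
        bank_to_frame(bank).to_csv(path, index=False)


def read_bank(path: str | Path, D: float = DEFAULT_D) -> ItemBank:
    """Read an item bank from CSV (`item_id,model,a,b1..`) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        items = tuple(
            ItemParameters(d["item_id"], d["a"], tuple(d["b"]), d.get("model", "GRM"))
            for d in doc["items"]
        )
        return ItemBank(items, D=float(doc.get("D", D)))
    df = pd.read_csv(path)
    missing_cols = [c for c in _BANK_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: bank file missing columns {missing_cols}")
    b_cols = sorted(
        (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    items = []
    for _, row in df.iterrows():
        b = tuple(float(row[c]) for c in b_cols if pd.notna(row[c]))
        model = row["model"] if isinstance(row.get("model"), str) else "GRM"
        items.append(ItemParameters(str(row["item_id"]), float(row["a"]), b, model))
    return ItemBank(tuple(items), D=D)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Result serialisation with provenance


def _provenance(seed: int | None, config: dict | None) -> dict:
    from . import __version__

    blob = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "package_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }


def write_results(
    payload: dict | list,
    path: str | Path,
    fmt: str = "json",
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write analysis results with a provenance block.

    JSON keeps full float precision; CSV renders floats at 6 significant
    digits and stores provenance in leading comment lines.
    """
    path = Path(path)
    prov = _provenance(seed, config)
    if fmt == "json":
        doc = {"provenance": prov, "results": payload}
        path.write_text(json.dumps(doc, indent=1, default=_json_default, sort_keys=True))
    elif fmt == "csv":
        rows = payload if isinstance(payload, list) else [payload]
        df = pd.DataFrame(rows)
        header = "".join(f"# {k}: {v}\n" for k, v in prov.items())
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.6g")
    else:
        raise ValueError(f"unknown results format {fmt!r}")


def read_results(path: str | Path) -> dict | list:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())["results"]
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    from io import StringIO

    return pd.read_csv(StringIO("".join(lines))).to_dict(orient="records")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    raise TypeError(f"cannot serialise {type(obj)}")
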