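"""Reading and writing encounter-history formats.

Supported formats:

* MARK-style ``.inp``: one record per line group, ``<history> <count>
  [<count> ...];`` with ``/* ... */`` comments; a negative count flags a
  loss on capture; several count columns encode groups.
* CSV, wide layout: one column per occasion plus optional ``count``,
  ``removed`` and ``group`` columns.
* CSV, long layout: ``individual``, ``occasion``, ``code`` triplets.
* YAML configuration for model specs and simulation scenarios.

Occasions are 1-based everywhere in user-facing files and reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .data import EncounterData
from .model_core import ModelSpec, ParameterSet
from .simulator import SimulationScenario


class ParseError(ValueError):
    """An input file violates its format."""


@dataclass(frozen=True)
class InpDialect:
    """The accepted flavour of MARK ``.inp`` files."""

    comment_open: str = "/*"
    comment_close: str = "*/"
    terminator: str = ";"
    negative_count_is_removal: bool = True


_DIALECT = InpDialect()


# ---------------------------------------------------------------------------
# MARK .inp
# ---------------------------------------------------------------------------

def read_inp(path, dialect: InpDialect = _DIALECT) -> EncounterData:
    """Parse a MARK-style ``.inp`` encounter-history file."""
    with open(path) as fh:
        raw = fh.read()
    # strip comments but keep newlines for line numbering
    def _blank(m):
        return re.sub(r"[^\n]", " ", m.group(0))
    no_comment = re.sub(
        re.escape(dialect.comment_open) + r".*?" + re.escape(dialect.comment_close),
        _blank, raw, flags=re.S,
    )

    # split into ';'-terminated records, remembering each record's first line
    records: list[tuple[list[str], int]] = []
    cur_tokens: list[str] = []
    cur_line: int | None = None
    for lineno, line in enumerate(no_comment.split("\n"), start=1):
        remaining = line
        while dialect.terminator in remaining:
            part, remaining = remaining.split(dialect.terminator, 1)
            toks = part.split()
            if toks and cur_line is None:
                cur_line = lineno
            cur_tokens.extend(toks)
            if cur_tokens:
                records.append((cur_tokens, cur_line if cur_line is not None else lineno))
            cur_tokens, cur_line = [], None
        toks = remaining.split()
        if toks and cur_line is None:
            cur_line = lineno
        cur_tokens.extend(toks)
    if cur_tokens:
        raise ParseError(f"line {cur_line}: record without terminator "
                         f"{dialect.terminator!r}")

    histories, counts, removed, groups = [], [], [], []
    width = None
    have_groups = False
    for tokens, lineno in records:
        hist = tokens[0]
        if not re.fullmatch(r"[012]+", hist):
            raise ParseError(f"line {lineno}: illegal characters in history {hist!r}")
        if width is None:
            width = len(hist)
        elif len(hist) != width:
            raise ParseError(
                f"line {lineno}: history length {len(hist)} != {width} (ragged)"
            )
        row = np.array([int(c) for c in hist], dtype=np.int8)
        col_counts = tokens[1:] or ["1"]
        if len(col_counts) > 1:
            have_groups = True
        for g, tok in enumerate(col_counts, start=1):
            try:
                c = int(tok)
            except ValueError as exc:
                raise ParseError(
                    f"line {lineno}: count {tok!r} is not an integer"
                ) from exc
            if c == 0:
                if len(col_counts) > 1:
                    continue  # empty cell of a group column
                raise ParseError(f"line {lineno}: zero count")
            rm = c < 0 and dialect.negative_count_is_removal
            histories.append(row)
            counts.append(abs(c))
            removed.append(rm)
            groups.append(f"group{g}")
    if not histories:
        raise ParseError("no records found")
    return EncounterData(
        np.vstack(histories), np.array(counts), np.array(removed),
        groups if have_groups else None,
    )


def write_inp(data: EncounterData, path, dialect: InpDialect = _DIALECT) -> None:
    """Write encounter data as ``.inp``; groups become count columns."""
    lines = [f"{dialect.comment_open} trapaware encounter histories {dialect.comment_close}"]
    if data.groups is None:
        for i in range(data.n_histories):
            hist = "".join(str(int(c)) for c in data.histories[i])
            cnt = int(data.counts[i]) * (-1 if data.removed[i] else 1)
            lines.append(f"{hist} {cnt}{dialect.terminator}")
    else:
        glabels = sorted(set(data.groups))
        cells: dict[tuple[bytes, bool], dict[str, int]] = {}
        order = []
        for i in range(data.n_histories):
            key = (data.histories[i].tobytes(), bool(data.removed[i]))
            if key not in cells:
                cells[key] = {}
                order.append(key)
            g = data.groups[i]
            cells[key][g] = cells[key].get(g, 0) + int(data.counts[i])
        K = data.n_occasions
        for key in order:
            hist = "".join(
                str(int(c)) for c in np.frombuffer(key[0], dtype=np.int8)[:K]
            )
            sign = -1 if key[1] else 1
            cols = " ".join(str(sign * cells[key].get(g, 0)) for g in glabels)
            lines.append(f"{hist} {cols}{dialect.terminator}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

_META_COLS = {"count", "removed", "group", "id", "individual"}


def read_csv(path, layout: str = "wide") -> EncounterData:
    """Read encounter histories from CSV in ``wide`` or ``long`` layout."""
    df = pd.read_csv(path)
    if layout == "wide":
        return _from_wide(df)
    if layout == "long":
        return _from_long(df)
    raise ParseError(f"unknown CSV layout {layout!r}")


def _validate_codes(values: np.ndarray, where: str) -> np.ndarray:
    arr = np.asarray(values)
    if np.issubdtype(arr.dtype, np.floating):
        if np.isnan(arr).any():
            raise ParseError(f"{where}: missing observation codes")
        if not np.allclose(arr, np.round(arr)):
            raise ParseError(f"{where}: non-integer observation codes")
        arr = arr.astype(int)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ParseError(f"{where}: non-integer observation codes")
    if not np.isin(arr, (0, 1, 2)).all():
        raise ParseError(f"{where}: observation codes must be 0, 1 or 2")
    return arr


def _from_wide(df: pd.DataFrame) -> EncounterData:
    occ_cols = [c for c in df.columns if c.strip().lower() not in _META_COLS]
    if not occ_cols:
        raise ParseError("wide CSV has no occasion columns")
    hist = _validate_codes(df[occ_cols].to_numpy(), "wide CSV").astype(np.int8)
    meta = {c.strip().lower(): c for c in df.columns if c.strip().lower() in _META_COLS}
    counts = df[meta["count"]].to_numpy(dtype=np.int64) if "count" in meta else None
    removed = df[meta["removed"]].astype(bool).to_numpy() if "removed" in meta else None
    groups = df[meta["group"]].astype(str).tolist() if "group" in meta else None
    return EncounterData(hist, counts, removed, groups)


def _from_long(df: pd.DataFrame) -> EncounterData:
    cols = {c.strip().lower(): c for c in df.columns}
    ind_col = cols.get("individual") or cols.get("id")
    if ind_col is None or "occasion" not in cols or "code" not in cols:
        raise ParseError("long CSV needs columns individual/id, occasion, code")
    dup = df.duplicated(subset=[ind_col, cols["occasion"]])
    if dup.any():
        raise ParseError(
            f"long CSV: duplicate (individual, occasion) cell at data row {int(dup.idxmax())}"
        )
    wide = df.pivot(index=ind_col, columns=cols["occasion"], values=cols["code"])
    if wide.isna().any().any():
        raise ParseError("long CSV: missing (individual, occasion) cells")
    occ = sorted(wide.columns)
    if occ != list(range(1, len(occ) + 1)):
        raise ParseError("long CSV: occasions must be 1..K with no gaps")
    hist = _validate_codes(wide[occ].to_numpy(), "long CSV").astype(np.int8)
    return EncounterData(hist)


def write_csv(data: EncounterData, path) -> None:
    """Write encounter data as wide CSV with count/removed (and group) columns."""
    K = data.n_occasions
    df = pd.DataFrame(data.histories, columns=[f"occ{t}" for t in range(1, K + 1)])
    df["count"] = data.counts
    df["removed"] = data.removed
    if data.groups is not None:
        df["group"] = data.groups
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def spec_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(
        n_occasions=int(d["n_occasions"]),
        state_space=d.get("state_space", "single"),
        effects_phi=frozenset(d.get("effects_phi", [])),
        effects_p=frozenset(d.get("effects_p", [])),
        censoring=bool(d.get("censoring", True)),
    )


def scenario_from_dict(d: dict) -> SimulationScenario:
    pkeys = {"phi", "phi1", "p", "p_prime", "m", "psi12", "psi21", "pi1"}
    pd_ = {k: v for k, v in d.get("params", {}).items() if k in pkeys}
    return SimulationScenario(
        n_occasions=int(d["n_occasions"]),
        n_released_per_cohort=d["n_released_per_cohort"],
        params=ParameterSet(**pd_),
        state_space=d.get("state_space", "single"),
        transient_fraction=float(d.get("transient_fraction", 0.0)),
        removal_prob=float(d.get("removal_prob", 0.0)),
        seed=int(d.get("seed", 0)),
    )


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
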