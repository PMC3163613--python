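"""CSV input, YAML/JSON design configs, and JSON report documents."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml

from . import __version__
from .designs import (
    DesignError,
    FRDesign,
    FRResponseSet,
    SSCDesign,
    SSCResponseSet,
    design_from_dict,
)

__all__ = [
    "ParseError",
    "read_responses",
    "load_design",
    "build_report",
    "write_report",
    "read_report",
]

_YES = {"yes", "y", "true", "1"}
_NO = {"no", "n", "false", "0"}


class ParseError(ValueError):
    """A response file could not be parsed; the message carries the line."""


def _line(idx: int) -> int:
    # data row idx 0 sits on file line 2 (after the header)
    return idx + 2


def read_responses(
    path: Union[str, Path],
    model: str = "ssc",
    m: Optional[int] = None,
) -> Union[SSCResponseSet, FRResponseSet]:
    """Read respondent data from CSV.

    Two layouts are accepted for either model: per-respondent (one row
    each: a ``total`` column for SSC, an ``answer`` yes/no column for FR)
    and aggregate (the same column plus a ``count`` column, one row per
    category). Totals outside ``0..m+1`` are a hard error when ``m`` is
    given.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    df.columns = [str(c).strip().lower() for c in df.columns]
    aggregate = "count" in df.columns
    if aggregate:
        counts = pd.to_numeric(df["count"], errors="coerce")
        bad = counts.isna() | (counts != counts.round()) | (counts < 0)
        if bad.any():
            raise ParseError(
                f"{path}: line {_line(int(bad.idxmax()))}: invalid count value"
            )
        counts = counts.astype(int)

    if model == "ssc":
        if "total" not in df.columns:
            raise ParseError(f"{path}: missing required column 'total'")
        totals = pd.to_numeric(df["total"], errors="coerce")
        bad = totals.isna() | (totals != totals.round()) | (totals < 0)
        if not bad.any() and m is not None:
            bad = totals > m + 1
        if bad.any():
            raise ParseError(
                f"{path}: line {_line(int(bad.idxmax()))}: "
                f"'total' must be an integer in 0..{'m+1' if m is None else m + 1}"
            )
        totals = totals.astype(int)
        if aggregate:
            return SSCResponseSet.from_counts(dict(zip(totals, counts)), m=m)
        return SSCResponseSet(totals.to_numpy(), m=m)

    if model == "fr":
        if "answer" not in df.columns:
            raise ParseError(f"{path}: missing required column 'answer'")
        answers = df["answer"].astype(str).str.strip().str.lower()
        unknown = ~answers.isin(_YES | _NO)
        if unknown.any():
            raise ParseError(
                f"{path}: line {_line(int(unknown.idxmax()))}: "
                f"'answer' must be yes/no, got {df['answer'][unknown.idxmax()]!r}"
            )
        is_yes = answers.isin(_YES)
        if aggregate:
            return FRResponseSet(
                n_yes=int(counts[is_yes].sum()), n=int(counts.sum())
            )
        return FRResponseSet(n_yes=int(is_yes.sum()), n=len(answers))

    raise ValueError(f"model: expected 'ssc' or 'fr', got {model!r}")


def load_design(path: Union[str, Path]) -> Union[SSCDesign, FRDesign]:
    """Load a design from a YAML (or JSON) config file.

    Recognised keys: ``model`` (ssc|fr), ``m``, ``probs`` (list or
    ``"equal"``), ``pi_forced_yes``, ``pi_forced_no``, ``pi_honest``;
    probabilities may be fractions like ``"1/6"``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise DesignError(f"{path}: design config must be a mapping")
    return design_from_dict(data)


def _config_hash(config: Optional[Mapping]) -> Optional[str]:
    if config is None:
        return None
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def build_report(
    estimate,
    input_summary: Mapping,
    t_test=None,
    planning: Optional[Mapping] = None,
    seed: Optional[int] = None,
    config: Optional[Mapping] = None,
) -> dict:
    """Assemble a JSON-serialisable report document for one analysis."""
    report = {
        "method": estimate.method if estimate is not None else None,
        "input": dict(input_summary),
        "estimate": estimate.to_dict() if estimate is not None else None,
        "provenance": {
            "package": "sscount",
            "version": __version__,
            "seed": seed,
            "config_hash": _config_hash(config),
        },
    }
    if t_test is not None:
        report["t_test"] = t_test.to_dict()
    if planning is not None:
        report["planning"] = dict(planning)
    return report


def write_report(report: Mapping, path: Union[str, Path]) -> None:
    """Write a report as pretty-printed JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_report(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        return json.load(fh)
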