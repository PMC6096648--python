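"""Reading study CSV files, config files, and serializing reports.

The flat study schema covers all three designs in one file::

    study_id,role,design,t,n1,n2,r,n,mean1,mean2,sd1,sd2

``role`` is ``original`` or ``replication``; columns a design does not
use stay blank. All numeric output is serialized with 6 significant
digits so repeated runs produce byte-identical, diffable text.
"""

from __future__ import annotations

import csv
import json
import math
from typing import Optional, TextIO

import pandas as pd
import yaml

from .effects import Design, StudySummary
from .evaluation import GridCondition
from .methods import GuidelineAdvice, MethodResult

STUDY_COLUMNS = ["study_id", "role", "design", "t", "n1", "n2", "r", "n",
                 "mean1", "mean2", "sd1", "sd2"]

_INT_FIELDS = {"n1", "n2", "n"}


def fmt(value) -> str:
    """Fixed 6-significant-digit formatting for all numeric output."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, (int,)) or (isinstance(value, float) and value.is_integer()
                                     and abs(value) < 1e15):
        return str(int(value))
    return f"{value:.6g}"


def _parse_row(row: dict, line_no: int) -> StudySummary:
    kwargs = {}
    design = (row.get("design") or "").strip()
    if not design:
        raise ValueError(f"line {line_no}: missing design")
    for name in ("t", "n1", "n2", "r", "n", "mean1", "mean2", "sd1", "sd2"):
        raw = (row.get(name) or "").strip()
        if raw == "":
            continue
        try:
            kwargs[name] = int(raw) if name in _INT_FIELDS else float(raw)
        except ValueError as exc:
            raise ValueError(f"line {line_no}: bad value for {name!r}: {raw!r}") from exc
    try:
        return StudySummary(design=Design(design), **kwargs)
    except ValueError as exc:
        raise ValueError(f"line {line_no}: {exc}") from exc


def read_study_pair_csv(handle: TextIO) -> tuple[StudySummary, StudySummary]:
    """Parse one original and one replication from a study CSV."""
    reader = csv.DictReader(_skip_comments(handle))
    studies = {}
    for line_no, row in enumerate(reader, start=2):
        role = (row.get("role") or "").strip()
        if role not in ("original", "replication"):
            raise ValueError(f"line {line_no}: role must be original or replication")
        if role in studies:
            raise ValueError(f"line {line_no}: duplicate {role} row")
        studies[role] = _parse_row(row, line_no)
    if set(studies) != {"original", "replication"}:
        raise ValueError("study CSV must contain exactly one original and one "
                         "replication row")
    return studies["original"], studies["replication"]


def _skip_comments(handle: TextIO):
    for line in handle:
        if not line.lstrip().startswith("#"):
            yield line


def write_pairs_csv(handle: TextIO, pairs: pd.DataFrame, design_n: tuple) -> None:
    """Serialize simulated Fisher-z pairs in the study CSV schema.

    Effects are written as correlations (design ``correlation``), two
    rows per pair, with the simulation metadata in a leading comment.
    """
    N_O, N_R = design_n
    meta = {k: pairs.attrs.get(k) for k in ("rho", "alpha", "seed")}
    handle.write(f"# simulated pairs rho={fmt(meta['rho'])} "
                 f"alpha={fmt(meta['alpha'])} seed={meta['seed']}\n")
    writer = csv.writer(handle)
    writer.writerow(STUDY_COLUMNS)
    for idx, row in pairs.iterrows():
        for role, y, n in (("original", row.y_original, N_O),
                           ("replication", row.y_replication, N_R)):
            writer.writerow([f"pair{idx + 1}", role, "correlation", "", "", "",
                             fmt(math.tanh(y)), n, "", "", "", ""])


def read_conditions(handle: TextIO) -> list[GridCondition]:
    """Grid conditions from a YAML (or JSON) config.

    Expected layout: a top-level ``conditions`` list of mappings with
    keys rho, N_O, N_R and optional alpha_one_tailed / grid_n / ci_level.
    """
    payload = yaml.safe_load(handle)
    if isinstance(payload, dict):
        payload = payload.get("conditions", [])
    if not isinstance(payload, list):
        raise ValueError("config must hold a list of conditions")
    out = []
    for i, entry in enumerate(payload, start=1):
        if not isinstance(entry, dict):
            raise ValueError(f"condition {i}: expected a mapping, got {entry!r}")
        try:
            out.append(GridCondition(**entry))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"condition {i}: {exc}") from exc
    return out


def results_to_json(results: dict[str, MethodResult],
                    advice: Optional[GuidelineAdvice] = None,
                    observed_power: Optional[float] = None,
                    report_scale: bool = True) -> str:
    payload = {}
    for name, res in results.items():
        rep = res.report() if report_scale else {
            "method": res.method.value, "estimate": res.estimate,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "statistic": res.statistic, "p_two_tailed": res.p_two_tailed,
            "ci_level": res.ci_level, "branch": res.branch_taken,
        }
        payload[name] = {
            k: (None if isinstance(v, float) and math.isnan(v)
                else float(fmt(v)) if isinstance(v, float) else v)
            for k, v in rep.items()
        }
    if advice is not None:
        payload["advice"] = {"recommended": advice.recommended.value,
                             "guideline": advice.guideline_id,
                             "rationale": advice.rationale}
    if observed_power is not None:
        payload["observed_power_original"] = float(fmt(observed_power))
    return json.dumps(payload, indent=2)


def results_to_text(results: dict[str, MethodResult],
                    advice: Optional[GuidelineAdvice] = None,
                    observed_power: Optional[float] = None) -> str:
    lines = [f"{'method':<14}{'estimate':>11}{'ci_low':>11}{'ci_high':>11}"
             f"{'stat':>11}{'p(2t)':>11}"]
    for name, res in results.items():
        rep = res.report()
        lines.append(f"{name:<14}{fmt(rep['estimate']):>11}{fmt(rep['ci_low']):>11}"
                     f"{fmt(rep['ci_high']):>11}{fmt(rep['statistic']):>11}"
                     f"{fmt(rep['p_two_tailed']):>11}")
    if observed_power is not None:
        lines.append(f"observed power of the original: {fmt(observed_power)}")
    if advice is not None:
        lines.append(f"guideline {advice.guideline_id}: interpret "
                     f"{advice.recommended.value} ({advice.rationale})")
    return "\n".join(lines)


def metrics_to_csv(table: pd.DataFrame) -> str:
    """Deterministic CSV for a tidy condition x method metric table."""
    out = table.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(fmt)
    return out.to_csv(index=False)
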