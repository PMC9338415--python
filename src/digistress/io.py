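"""File formats: JSONL session logs, questionnaire/summary CSVs, manifests,
and JSON reports.

Session logs are JSON Lines (UTF-8, one event object per line) with a
mandatory header line carrying ``schema_version``, the condition, the seed,
and a config snapshot.  Reports serialize with sorted keys so fixed-seed
pipelines are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import datetime
import importlib.resources
import json
from pathlib import Path

import pandas as pd

from .protocol import SCHEMA_VERSION, SessionEvent, SessionLog
from .stats import MetaInput

# ---------------------------------------------------------------------------
# session logs


def session_log_to_jsonl(log: SessionLog) -> str:
    header = dict(log.metadata)
    header.setdefault("schema_version", SCHEMA_VERSION)
    lines = [json.dumps(header, sort_keys=True)]
    for ev in log.events:
        lines.append(json.dumps({"t": ev.t, "type": ev.type, "payload": ev.payload},
                                sort_keys=True))
    return "\n".join(lines) + "\n"


def session_log_from_jsonl(text: str) -> SessionLog:
    lines = text.splitlines()
    if not lines:
        raise ValueError("empty session log")

    def parse(i: int) -> dict:
        try:
            return json.loads(lines[i])
        except json.JSONDecodeError as err:
            raise ValueError(f"malformed JSONL at line {i + 1}: {err}") from None

    header = parse(0)
    version = header.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported session-log schema_version: {version!r} "
                         f"(expected {SCHEMA_VERSION})")
    events = []
    for i in range(1, len(lines)):
        if not lines[i].strip():
            continue
        d = parse(i)
        if not {"t", "type"} <= d.keys():
            raise ValueError(f"event at line {i + 1} lacks 't'/'type'")
        events.append(SessionEvent(t=float(d["t"]), type=d["type"],
                                   payload=d.get("payload", {})))
    return SessionLog(metadata=header, events=events)


def write_session_log(log: SessionLog, path) -> None:
    Path(path).write_text(session_log_to_jsonl(log), encoding="utf-8")


def read_session_log(path) -> SessionLog:
    return session_log_from_jsonl(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# tabular data


def write_questionnaire_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, lineterminator="\n")


def read_questionnaire_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant", "group", "time", "measure", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"questionnaire CSV lacks columns: {sorted(missing)}")
    bad = df[df["value"].isna()]
    if not bad.empty:
        raise ValueError(f"non-numeric value at CSV row {int(bad.index[0]) + 2}")
    return df


_TABLE2_REQUIRED = {"study", "subscale", "pre_mean", "pre_sd", "post_mean",
                    "post_sd", "change_mean", "change_sd", "n"}


def load_table2(path=None) -> pd.DataFrame:
    """Load a per-study summary table (bundled fixture when no path given).

    The bundled file transcribes the published pre/post/change summary
    statistics of the stress-test arm and the four laboratory comparison
    studies, one row per study x PANAS subscale.
    """
    # keep_default_na: the negative-affect subscale is literally named "NA"
    kwargs = {"keep_default_na": False, "na_values": [""]}
    if path is None:
        ref = importlib.resources.files("digistress.data") / "table2.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, **kwargs)
    else:
        df = pd.read_csv(path, **kwargs)
    missing = _TABLE2_REQUIRED - set(df.columns)
    if missing:
        raise ValueError(f"summary CSV lacks columns: {sorted(missing)}")
    return df


def meta_inputs_from_table(df: pd.DataFrame, subscale: str,
                           variant: str = "printed",
                           paradigm: str | None = "TSST") -> list[MetaInput]:
    """Build meta-analysis inputs from a summary table.

    ``variant`` selects the per-study effect size: ``printed`` uses the
    table's own d column, ``change_sd`` recomputes change_mean/change_sd, and
    ``pooled_prepost`` recomputes from pre/post summaries.  ``paradigm``
    filters rows (the published combination covers the laboratory studies
    only); pass None to keep all rows.
    """
    from .stats import cohen_d_change, cohen_d_pooled_prepost

    sub = df[df["subscale"] == subscale]
    if paradigm is not None and "paradigm" in df.columns:
        sub = sub[sub["paradigm"] == paradigm]
    if sub.empty:
        raise ValueError(f"no rows for subscale {subscale!r}")
    inputs = []
    for _, row in sub.iterrows():
        if variant == "printed":
            if "d_printed" not in row:
                raise ValueError("summary CSV lacks a d_printed column")
            d = float(row["d_printed"])
        elif variant == "change_sd":
            d = cohen_d_change(row["change_mean"], row["change_sd"]).d
        elif variant == "pooled_prepost":
            d = cohen_d_pooled_prepost(row["pre_mean"], row["pre_sd"],
                                       row["post_mean"], row["post_sd"]).d
        else:
            raise ValueError(f"unknown variant {variant!r}")
        inputs.append(MetaInput(label=str(row["study"]), d=d,
                                change_sd=float(row["change_sd"]),
                                n=int(row["n"])))
    return inputs


# ---------------------------------------------------------------------------
# reports and manifests


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_report_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2,
                                     default=_jsonable) + "\n", encoding="utf-8")


def report_text(report: dict) -> str:
    """Human-readable rendering of an evaluate_study report."""
    lines = []
    for measure, entry in sorted(report.get("measures", {}).items()):
        lines.append(f"== {measure} ==")
        for eff in entry.get("anova", []):
            extra = ""
            if eff.get("gg_epsilon") is not None:
                extra = f", GG eps={eff['gg_epsilon']:.3f}"
                if eff.get("p_gg") is not None:
                    extra += f", p_GG={eff['p_gg']:.4g}"
            lines.append(
                f"  {eff['effect']:<12s} F({eff['df1']:g},{eff['df2']:g}) = "
                f"{eff['F']:.2f}, p = {eff['p']:.4g}, "
                f"eta_p^2 = {eff['partial_eta2']:.3f}{extra}")
        for ph in entry.get("posthoc", []):
            lines.append(
                f"  post hoc {ph['time']:<12s} Welch t({ph['df']:.1f}) = "
                f"{ph['t']:.2f}, p_bonf = {ph['p_bonf']:.4g}")
        for group, es in sorted(entry.get("effect_sizes", {}).items()):
            d_pool = es.get("d_pooled_prepost")
            d_z = es.get("d_change_sd")
            lines.append(
                f"  {group}: change {es['change_mean']:+.3f} "
                f"(SD {es['change_sd']:.3f}), "
                f"d_pooled = {d_pool:.3f}" if d_pool is not None else
                f"  {group}: change {es['change_mean']:+.3f}")
            if d_z is not None:
                lines[-1] += f", d_z = {d_z:.3f}"
    return "\n".join(lines) + "\n"


def write_manifest(out_dir, command: str, seed, config_snapshot: dict | None = None,
                   inputs=None, outputs=None) -> Path:
    """Write the single run manifest of an output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "command": command,
        "seed": seed,
        "config": config_snapshot or {},
        "inputs": [str(p) for p in (inputs or [])],
        "outputs": [str(p) for p in (outputs or [])],
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n",
                    encoding="utf-8")
    return path
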