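"""Trial annotations: CSV and Praat TextGrid reading/writing.

Annotations are tidy rows (trial_id, task, onset_s, offset_s) with task in
{vowel, ddk, sentence}. The TextGrid layout mirrors how a speech-language
pathologist timestamps trials in Praat: one interval tier per task, labelled
intervals marking each production. Both the long ("ooTextFile" with item
blocks) and short TextGrid text formats are parsed; no third-party TextGrid
library is available in this stack, so the parser lives here.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import TASKS, annotations_frame

_LABEL_ALIASES = {
    "vowel": "vowel", "a": "vowel", "ah": "vowel",
    "ddk": "ddk", "diadochokinesis": "ddk", "tatata": "ddk",
    "sentence": "sentence", "sentence repetition": "sentence",
}


def normalize_task(label: str) -> str:
    key = label.strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(f"unknown task label {label!r}; expected one of "
                         f"{sorted(set(_LABEL_ALIASES))}")
    return _LABEL_ALIASES[key]


def write_events_csv(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, index=False)


def _read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"trial_id", "task", "onset_s", "offset_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events CSV is missing columns: {sorted(missing)}")
    bad = df.index[df["offset_s"] <= df["onset_s"]]
    if len(bad):
        raise ValueError(f"offset must exceed onset; offending rows: {list(bad)}")
    tasks = [normalize_task(t) for t in df["task"]]
    return annotations_frame(df["trial_id"], tasks, df["onset_s"], df["offset_s"])


def write_textgrid(annotations: pd.DataFrame, path, xmax: float | None = None) -> None:
    """Long-format TextGrid with one interval tier per task."""
    if xmax is None:
        xmax = float(annotations["offset_s"].max()) + 1.0
    lines = ['File type = "ooTextFile"', 'Object class = "TextGrid"', "",
             "xmin = 0", f"xmax = {xmax:.6f}", "tiers? <exists>",
             f"size = {len(TASKS)}", "item []:"]
    for ti, task in enumerate(TASKS, start=1):
        sub = annotations[annotations["task"] == task].sort_values("onset_s")
        intervals = []
        t = 0.0
        for row in sub.itertuples(index=False):
            if row.onset_s > t:
                intervals.append((t, row.onset_s, ""))
            intervals.append((row.onset_s, row.offset_s, task))
            t = row.offset_s
        if t < xmax:
            intervals.append((t, xmax, ""))
        lines += [f"    item [{ti}]:", '        class = "IntervalTier"',
                  f'        name = "{task}"', "        xmin = 0",
                  f"        xmax = {xmax:.6f}",
                  f"        intervals: size = {len(intervals)}"]
        for ii, (a, b, lab) in enumerate(intervals, start=1):
            lines += [f"        intervals [{ii}]:", f"            xmin = {a:.6f}",
                      f"            xmax = {b:.6f}", f'            text = "{lab}"']
    Path(path).write_text("\n".join(lines) + "\n")


_NUM = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")


def _parse_textgrid_long(text: str):
    tiers = []
    for block in re.split(r"item \[\d+\]:", text)[1:]:
        name_m = re.search(r'name\s*=\s*"([^"]*)"', block)
        name = name_m.group(1) if name_m else ""
        intervals = []
        for iv in re.split(r"intervals \[\d+\]:", block)[1:]:
            xmin = float(_NUM.search(re.search(r"xmin\s*=\s*(\S+)", iv).group(1)).group())
            xmax = float(_NUM.search(re.search(r"xmax\s*=\s*(\S+)", iv).group(1)).group())
            lab = re.search(r'text\s*=\s*"([^"]*)"', iv).group(1)
            intervals.append((xmin, xmax, lab))
        tiers.append((name, intervals))
    return tiers


def _parse_textgrid_short(text: str):
    # short format: positional tokens after the 8-line preamble
    tokens = [ln.strip() for ln in text.splitlines() if ln.strip()]
    it = iter(tokens[6:])  # skip file type, class, xmin, xmax, exists, size
    tiers = []
    try:
        while True:
            tclass = next(it).strip('"')
            if tclass != "IntervalTier":
                raise ValueError(f"unsupported tier class {tclass!r}")
            name = next(it).strip('"')
            next(it); next(it)  # tier xmin, xmax
            n = int(next(it))
            intervals = []
            for _ in range(n):
                a, b = float(next(it)), float(next(it))
                lab = next(it).strip('"')
                intervals.append((a, b, lab))
            tiers.append((name, intervals))
    except StopIteration:
        pass
    return tiers


def read_textgrid(path) -> pd.DataFrame:
    """Annotations from a TextGrid: labelled intervals become trials."""
    text = Path(path).read_text()
    tiers = (_parse_textgrid_long(text) if "item [" in text
             else _parse_textgrid_short(text))
    rows = []
    for name, intervals in tiers:
        labelled = [(a, b, lab) for a, b, lab in intervals if lab.strip()]
        for (a0, b0, l0), (a1, b1, l1) in zip(labelled, labelled[1:]):
            if a1 < b0 - 1e-9:
                raise ValueError(
                    f"overlapping intervals on tier {name!r}: "
                    f"({a0:.3f},{b0:.3f},{l0!r}) and ({a1:.3f},{b1:.3f},{l1!r})")
        for a, b, lab in labelled:
            rows.append({"task": normalize_task(lab), "onset_s": a, "offset_s": b})
    rows.sort(key=lambda r: r["onset_s"])
    return annotations_frame(np.arange(len(rows)),
                             [r["task"] for r in rows],
                             [r["onset_s"] for r in rows],
                             [r["offset_s"] for r in rows])


def read_events(path, format: str | None = None) -> pd.DataFrame:
    """Read annotations from CSV or TextGrid (format inferred from suffix)."""
    if format is None:
        format = "textgrid" if str(path).lower().endswith(".textgrid") else "csv"
    if format == "csv":
        return _read_events_csv(path)
    if format == "textgrid":
        return read_textgrid(path)
    raise ValueError(f"unknown events format {format!r}")
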