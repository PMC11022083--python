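"""Reader/writer for the three-text-file recording layout.

A recording ``<base>`` is stored as three plain-text files:

``<base>.data.tsv``
    One row per sample, tab-separated with a one-line header and
    ``#``-prefixed comment lines: ``sample_id  block_id  event_id  t  ax ay
    az  [raw_x raw_y raw_z]  [temperature]``. The optional raw-count and
    temperature columns are omitted entirely when absent. Floats are
    written with Python's shortest round-tripping repr, so write→read is
    bit-exact.

``<base>.time.tsv``
    One row per sample: ``sample_id``, ISO-8601 wall-clock stamp with
    millisecond precision, and a marker column (empty, ``break`` or
    ``delay``) that makes inter-block pauses and trigger delays visible.

``<base>.meta.txt``
    Flat ``key=value`` lines: subject fields (``subject.*``), block/event
    summary counts, hardware (``hardware.*``) and protocol (``protocol.*``)
    configuration, creation stamp and the calibration flag.

This dialect is a documented re-design, not a reverse-engineered match of
the original acquisition software's files, whose exact column layout was
never published.
"""

from __future__ import annotations

from dataclasses import fields as dc_fields
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    Block,
    Event,
    HardwareConfig,
    ProtocolConfig,
    Recording,
    RecordingMeta,
    ValidationError,
    validate_recording,
)

DATA_SUFFIX = ".data.tsv"
TIME_SUFFIX = ".time.tsv"
META_SUFFIX = ".meta.txt"

_FORMAT_TAG = "limbkin-recording-v1"
_DATA_COLS = ["sample_id", "block_id", "event_id", "t", "ax", "ay", "az"]
_RAW_COLS = ["raw_x", "raw_y", "raw_z"]


class ParseError(ValueError):
    """A stored recording file could not be parsed."""


# ---------------------------------------------------------------------------
# writing


def _fmt_datetime(ts: datetime | np.datetime64) -> str:
    if isinstance(ts, np.datetime64):
        ts = ts.astype("datetime64[ms]").astype(datetime)
    return ts.strftime("%Y-%m-%dT%H:%M:%S.") + f"{ts.microsecond // 1000:03d}"


def _meta_lines(meta: RecordingMeta) -> list[str]:
    lines = [f"format={_FORMAT_TAG}"]
    if meta.created is not None:
        lines.append(f"created={_fmt_datetime(meta.created)}")
    lines.append(f"n_blocks={meta.n_blocks}")
    lines.append(f"n_events={meta.n_events}")
    lines.append(f"calibrated={'true' if meta.calibrated else 'false'}")
    for key, value in meta.subject.items():
        if "\n" in str(value) or "=" in key:
            raise ValidationError(f"subject field {key!r} contains unsupported characters")
        lines.append(f"subject.{key}={value}")
    if meta.hardware is not None:
        for f in dc_fields(HardwareConfig):
            lines.append(f"hardware.{f.name}={getattr(meta.hardware, f.name)}")
    if meta.protocol is not None:
        for f in dc_fields(ProtocolConfig):
            lines.append(f"protocol.{f.name}={getattr(meta.protocol, f.name)}")
    return lines


def write_recording(rec: Recording, basepath: str | Path) -> tuple[Path, Path, Path]:
    """Write ``rec`` to ``<basepath>.data.tsv/.time.tsv/.meta.txt``.

    The recording is validated first; any invariant violation raises
    :class:`~limbkin.model.ValidationError` naming the first offending
    sample/event, and nothing is written.

    Returns the three file paths (data, time, meta).
    """
    problems = validate_recording(rec)
    if problems:
        raise ValidationError(problems[0])

    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    data_path = basepath.with_name(basepath.name + DATA_SUFFIX)
    time_path = basepath.with_name(basepath.name + TIME_SUFFIX)
    meta_path = basepath.with_name(basepath.name + META_SUFFIX)

    events = list(rec.iter_events())
    has_raw = bool(events) and all(e.raw is not None for e in events)
    has_temp = bool(events) and all(e.temperature is not None for e in events)
    # mixed presence across events is structurally suspect; refuse it
    if events and not has_raw and any(e.raw is not None for e in events):
        raise ValidationError("raw counts present in some events but not all")
    if events and not has_temp and any(e.temperature is not None for e in events):
        raise ValidationError("temperature present in some events but not all")

    cols: dict[str, np.ndarray] = {}
    if events:
        cols["sample_id"] = np.concatenate([e.sample_ids for e in events])
        cols["block_id"] = np.concatenate(
            [np.full(e.n_samples, e.block_id, dtype=np.int64) for e in events]
        )
        cols["event_id"] = np.concatenate(
            [np.full(e.n_samples, e.event_id, dtype=np.int64) for e in events]
        )
        cols["t"] = np.concatenate([e.t for e in events])
        accel = np.concatenate([e.accel for e in events])
        cols["ax"], cols["ay"], cols["az"] = accel[:, 0], accel[:, 1], accel[:, 2]
        if has_raw:
            raw = np.concatenate([e.raw for e in events])
            cols["raw_x"], cols["raw_y"], cols["raw_z"] = raw[:, 0], raw[:, 1], raw[:, 2]
        if has_temp:
            cols["temperature"] = np.concatenate([e.temperature for e in events])
    df = pd.DataFrame(cols)
    if df.empty:
        df = pd.DataFrame(columns=_DATA_COLS)

    with open(data_path, "w") as fh:
        fh.write(f"# {_FORMAT_TAG} data file: one row per sample, acceleration in m/s^2\n")
        df.to_csv(fh, sep="\t", index=False)

    with open(time_path, "w") as fh:
        fh.write(f"# {_FORMAT_TAG} timestamp file: per-sample wall clock and markers\n")
        fh.write("sample_id\ttimestamp\tmarker\n")
        if rec.timestamps is not None and events:
            sids = cols["sample_id"]
            markers = rec.markers or [""] * len(sids)
            stamps = [_fmt_datetime(ts) for ts in rec.timestamps]
            fh.writelines(
                f"{sid}\t{stamp}\t{marker}\n"
                for sid, stamp, marker in zip(sids, stamps, markers)
            )

    with open(meta_path, "w") as fh:
        fh.write(f"# {_FORMAT_TAG} metadata file\n")
        fh.writelines(line + "\n" for line in _meta_lines(rec.meta))

    return data_path, time_path, meta_path


def export_csv(rec: Recording, path: str | Path) -> Path:
    """Export the per-sample data table as a single comma-separated file."""
    path = Path(path)
    rows = []
    for e in rec.iter_events():
        frame = {
            "sample_id": e.sample_ids,
            "block_id": e.block_id,
            "event_id": e.event_id,
            "t": e.t,
            "ax": e.accel[:, 0],
            "ay": e.accel[:, 1],
            "az": e.accel[:, 2],
        }
        rows.append(pd.DataFrame(frame))
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=_DATA_COLS)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# reading


def _parse_bool(s: str) -> bool:
    return s.strip().lower() in ("true", "1", "yes")


def _parse_meta(path: Path) -> RecordingMeta:
    pairs: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(f"{path.name}:{lineno}: expected key=value, got {line!r}")
        key, value = line.split("=", 1)
        pairs[key.strip()] = value
    meta = RecordingMeta()
    meta.n_blocks = int(pairs.get("n_blocks", 0))
    meta.n_events = int(pairs.get("n_events", 0))
    meta.calibrated = _parse_bool(pairs.get("calibrated", "false"))
    if "created" in pairs:
        meta.created = datetime.fromisoformat(pairs["created"])
    meta.subject = {
        k[len("subject."):]: v for k, v in pairs.items() if k.startswith("subject.")
    }
    hw = {k[len("hardware."):]: v for k, v in pairs.items() if k.startswith("hardware.")}
    if hw:
        meta.hardware = HardwareConfig(
            range_g=int(hw["range_g"]),
            sampling_rate_hz=float(hw["sampling_rate_hz"]),
            highpass_enabled=_parse_bool(hw["highpass_enabled"]),
            highpass_cutoff_hz=float(hw["highpass_cutoff_hz"]),
            beep_duration_ms=float(hw["beep_duration_ms"]),
            trigger_edge=hw["trigger_edge"],
        )
    pr = {k[len("protocol."):]: v for k, v in pairs.items() if k.startswith("protocol.")}
    if pr:
        meta.protocol = ProtocolConfig(
            mode=pr["mode"],
            stim_rate_mHz=float(pr["stim_rate_mHz"]),
            block_duration_s=float(pr["block_duration_s"]),
            pause_s=float(pr["pause_s"]),
            repetitions=int(pr["repetitions"]),
            event_samples=int(pr["event_samples"]),
            sampling_rate_hz=float(pr["sampling_rate_hz"]),
            trigger_edge=pr["trigger_edge"],
            beep_on_trigger=_parse_bool(pr["beep_on_trigger"]),
        )
    return meta


def read_recording(basepath: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Optional columns (raw counts, temperature) that are absent from the
    data file yield absent fields on the events, never zeros. Malformed
    rows raise :class:`ParseError`; structural problems (ID gaps,
    non-monotone IDs, count mismatches) raise
    :class:`~limbkin.model.ValidationError`.
    """
    basepath = Path(basepath)
    data_path = basepath.with_name(basepath.name + DATA_SUFFIX)
    time_path = basepath.with_name(basepath.name + TIME_SUFFIX)
    meta_path = basepath.with_name(basepath.name + META_SUFFIX)
    for p in (data_path, time_path, meta_path):
        if not p.exists():
            raise FileNotFoundError(f"missing recording file: {p}")

    meta = _parse_meta(meta_path)

    try:
        df = pd.read_csv(
            data_path, sep="\t", comment="#", float_precision="round_trip"
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{data_path.name}: {exc}") from exc
    missing = [c for c in _DATA_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{data_path.name}: missing required columns {missing}")
    for col in ("sample_id", "block_id", "event_id"):
        if len(df) and not np.issubdtype(df[col].dtype, np.integer):
            bad = int(np.argmax(~np.isfinite(pd.to_numeric(df[col], errors="coerce"))))
            raise ParseError(
                f"{data_path.name}: non-integer value in column {col!r} "
                f"near data row {bad + 1}"
            )
    has_raw = all(c in df.columns for c in _RAW_COLS)
    has_temp = "temperature" in df.columns

    try:
        tdf = pd.read_csv(
            time_path,
            sep="\t",
            comment="#",
            dtype={"sample_id": np.int64, "marker": str},
            keep_default_na=False,
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{time_path.name}: {exc}") from exc
    timestamps: np.ndarray | None = None
    markers: list[str] | None = None
    if len(tdf):
        if len(tdf) != len(df):
            raise ValidationError(
                f"timestamp file has {len(tdf)} rows but data file has {len(df)} samples"
            )
        try:
            timestamps = pd.to_datetime(tdf["timestamp"]).to_numpy().astype("datetime64[ms]")
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{time_path.name}: bad timestamp: {exc}") from exc
        markers = [m.strip() for m in tdf["marker"].tolist()]

    # rebuild the block/event hierarchy in file order
    blocks: list[Block] = []
    if len(df):
        sid_all = df["sample_id"].to_numpy(dtype=np.int64)
        boundaries = np.flatnonzero(
            np.diff(df["block_id"].to_numpy() * (2**32) + df["event_id"].to_numpy())
        )
        starts = np.concatenate([[0], boundaries + 1])
        ends = np.concatenate([boundaries + 1, [len(df)]])
        cur_block: Block | None = None
        for s, e in zip(starts, ends):
            bid = int(df["block_id"].iloc[s])
            eid = int(df["event_id"].iloc[s])
            if cur_block is None or cur_block.block_id != bid:
                cur_block = Block(block_id=bid)
                blocks.append(cur_block)
            trig = None
            if timestamps is not None:
                trig = timestamps[s].astype("datetime64[ms]").astype(datetime)
            cur_block.events.append(
                Event(
                    event_id=eid,
                    block_id=bid,
                    sample_ids=sid_all[s:e],
                    t=df["t"].to_numpy(dtype=np.float64)[s:e],
                    accel=df[["ax", "ay", "az"]].to_numpy(dtype=np.float64)[s:e],
                    raw=df[_RAW_COLS].to_numpy(dtype=np.int64)[s:e] if has_raw else None,
                    temperature=(
                        df["temperature"].to_numpy(dtype=np.float64)[s:e]
                        if has_temp
                        else None
                    ),
                    trigger_time=trig,
                )
            )

    rec = Recording(blocks, meta, timestamps=timestamps, markers=markers)
    problems = validate_recording(rec)
    if problems:
        raise ValidationError(problems[0])
    return rec
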