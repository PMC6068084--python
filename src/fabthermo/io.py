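"""Readers and writers for the package's plain-text formats.

Sensorgram dialect: a CSV file with ``#``-prefixed ``key=value`` header
lines followed by a ``time_s,response_RU`` column header and data rows.
Mandatory header keys: ``concentration_M``, ``temperature_K`` and
``phase_assoc_end_s``; ``phase_assoc_start_s`` is optional (default 0).
Times must be strictly increasing; trailing blank lines are tolerated.
Floats are written with ``repr`` so a write/read round trip is exact.

Manifests and pipeline configurations are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .binding import SensorgramTrace

_REQUIRED_KEYS = ("concentration_M", "temperature_K", "phase_assoc_end_s")


class SensorgramParseError(ValueError):
    """Malformed sensorgram file; the message names the offending line."""


def write_sensorgram(trace: SensorgramTrace, path) -> None:
    """Write a trace in the package's sensorgram CSV dialect."""
    path = Path(path)
    lines = [
        f"# concentration_M={float(trace.concentration)!r}",
        f"# temperature_K={float(trace.temperature)!r}",
        f"# phase_assoc_start_s={float(trace.t_assoc_start)!r}",
        f"# phase_assoc_end_s={float(trace.t_assoc_end)!r}",
        "time_s,response_RU",
    ]
    lines += [f"{float(t)!r},{float(r)!r}" for t, r in zip(trace.times, trace.responses)]
    path.write_text("\n".join(lines) + "\n")


def read_sensorgram(path) -> SensorgramTrace:
    """Read a sensorgram CSV, validating headers and monotone time."""
    path = Path(path)
    header: dict[str, float] = {}
    times: list[float] = []
    responses: list[float] = []
    saw_columns = False

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" not in body:
                raise SensorgramParseError(f"{path.name}:{lineno}: malformed header line {raw!r}")
            key, _, value = body.partition("=")
            try:
                header[key.strip()] = float(value)
            except ValueError as exc:
                raise SensorgramParseError(
                    f"{path.name}:{lineno}: non-numeric header value {value!r}"
                ) from exc
            continue
        if not saw_columns:
            if line.replace(" ", "") != "time_s,response_RU":
                raise SensorgramParseError(
                    f"{path.name}:{lineno}: expected column header 'time_s,response_RU', got {raw!r}"
                )
            saw_columns = True
            continue
        cells = line.split(",")
        if len(cells) != 2:
            raise SensorgramParseError(f"{path.name}:{lineno}: expected two cells, got {raw!r}")
        try:
            times.append(float(cells[0]))
            responses.append(float(cells[1]))
        except ValueError as exc:
            raise SensorgramParseError(f"{path.name}:{lineno}: non-numeric cell in {raw!r}") from exc

    missing = [k for k in _REQUIRED_KEYS if k not in header]
    if missing:
        raise SensorgramParseError(f"{path.name}: missing mandatory header keys {missing}")
    t = np.asarray(times)
    if t.size < 2:
        raise SensorgramParseError(f"{path.name}: fewer than 2 data rows")
    if np.any(np.diff(t) <= 0):
        bad = int(np.nonzero(np.diff(t) <= 0)[0][0])
        raise SensorgramParseError(f"{path.name}: time not strictly increasing at row {bad + 2}")

    return SensorgramTrace(
        times=t,
        responses=np.asarray(responses),
        concentration=header["concentration_M"],
        temperature=header["temperature_K"],
        t_assoc_start=header.get("phase_assoc_start_s", 0.0),
        t_assoc_end=header["phase_assoc_end_s"],
        label=path.stem,
    )


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def read_config(path) -> dict:
    """Read a pipeline configuration (YAML)."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (identifier, sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
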