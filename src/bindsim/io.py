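"""File formats and run metadata.

Energy matrices travel as TSV (4 labeled base rows x m position columns, kT,
optional ``#offset`` line).  Probability matrices travel either as a MEME
minimal-motif file or as a TSV mirroring the energy-matrix layout.  All
numbers are serialized at repr precision so write/read round-trips are exact.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .energy import BASES, EnergyMatrix, GAUGE_TOL
from .pm import ProbabilityMatrix


class ParseError(ValueError):
    """Raised for malformed model files; message names the offending line."""


# ---------------------------------------------------------------------------
# energy-matrix TSV

def write_energy_matrix(model: EnergyMatrix, path) -> None:
    path = Path(path)
    lines = [f"#offset {model.offset!r}"]
    lines.append("pos\t" + "\t".join(str(j + 1) for j in range(model.m)))
    for i, b in enumerate(BASES):
        lines.append(b + "\t" + "\t".join(repr(float(v)) for v in model.eps[i]))
    path.write_text("\n".join(lines) + "\n")


def read_energy_matrix(path) -> EnergyMatrix:
    """Read an energy-matrix TSV; re-gauges (with a warning) if any column
    minimum is nonzero, moving the residue into the offset."""
    path = Path(path)
    offset = 0.0
    rows: dict[str, list[float]] = {}
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#offset"):
            try:
                offset = float(line.split(None, 1)[1])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed #offset line") from exc
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].lower() == "pos":
            header_seen = True
            continue
        label = fields[0].upper()
        if label not in BASES:
            raise ParseError(f"{path}:{lineno}: unexpected row label {fields[0]!r} (want A/C/G/T)")
        if label in rows:
            raise ParseError(f"{path}:{lineno}: duplicate row for base {label}")
        try:
            rows[label] = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric entry in row {label}") from exc
    if not header_seen:
        raise ParseError(f"{path}: missing 'pos' header line")
    missing = [b for b in BASES if b not in rows]
    if missing:
        raise ParseError(f"{path}: missing rows for bases {missing}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1 or 0 in lengths:
        raise ParseError(f"{path}: base rows have inconsistent or zero lengths")
    eps = np.array([rows[b] for b in BASES])
    mins = eps.min(axis=0)
    if np.any(np.abs(mins) > GAUGE_TOL):
        warnings.warn(
            f"{path}: energy matrix violates the zero gauge; re-gauged "
            f"(column minima moved into the offset, total {mins.sum():.6g} kT)",
            stacklevel=2,
        )
        return EnergyMatrix.from_array(eps, offset, regauge=True)
    return EnergyMatrix(eps, offset)


# ---------------------------------------------------------------------------
# probability-matrix formats

#: column sums off by more than this are a parse error; smaller drift is
#: silently renormalized
PM_SUM_TOL = 1e-6


def write_pm(pm: ProbabilityMatrix, path, fmt: str | None = None, name: str = "pm1") -> None:
    """Write a probability matrix as MEME minimal motif format or TSV.

    ``fmt`` is inferred from the extension when omitted: ``.meme``/``.txt``
    write MEME, anything else TSV.
    """
    path = Path(path)
    if fmt is None:
        fmt = "meme" if path.suffix.lower() in (".meme", ".txt") else "tsv"
    if fmt == "meme":
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            "Background letter frequencies",
            " ".join(f"{b} {float(pm.background[i])!r}" for i, b in enumerate(BASES)),
            "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {pm.m} nsites= 20 E= 0",
        ]
        for j in range(pm.m):
            lines.append(" " + " ".join(repr(float(v)) for v in pm.probs[:, j]))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "tsv":
        lines = ["pos\t" + "\t".join(str(j + 1) for j in range(pm.m))]
        for i, b in enumerate(BASES):
            lines.append(b + "\t" + "\t".join(repr(float(v)) for v in pm.probs[i]))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown PM format {fmt!r}")


def _normalize_columns(probs: np.ndarray, where: str) -> np.ndarray:
    sums = probs.sum(axis=0)
    bad = np.abs(sums - 1) > PM_SUM_TOL
    if bad.any():
        raise ParseError(
            f"{where}: probability columns {list(np.nonzero(bad)[0] + 1)} sum to "
            f"{sums[bad].round(6).tolist()}, beyond tolerance {PM_SUM_TOL}"
        )
    return probs / sums


def read_pm(path, fmt: str | None = None) -> ProbabilityMatrix:
    """Read a probability matrix (MEME minimal or TSV).

    Columns whose sums are within ``PM_SUM_TOL`` of 1 are renormalized;
    larger deviations raise :class:`ParseError`.
    """
    path = Path(path)
    text = path.read_text()
    if fmt is None:
        fmt = "meme" if "letter-probability matrix" in text else "tsv"
    if fmt == "meme":
        return _read_pm_meme(path, text)
    return _read_pm_tsv(path, text)


def _read_pm_meme(path: Path, text: str) -> ProbabilityMatrix:
    lines = text.splitlines()
    background = np.full(4, 0.25)
    i = 0
    rows: list[list[float]] = []
    w = None
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freq = {toks[k].upper(): float(toks[k + 1]) for k in range(0, len(toks), 2)}
            background = np.array([freq[b] for b in BASES])
        elif line.startswith("letter-probability matrix"):
            toks = line.split()
            if "w=" in toks:
                w = int(toks[toks.index("w=") + 1])
            i += 1
            while i < len(lines) and lines[i].strip() and not lines[i].strip().startswith("MOTIF"):
                vals = lines[i].split()
                if len(vals) != 4:
                    raise ParseError(f"{path}:{i + 1}: expected 4 probabilities per matrix row")
                rows.append([float(v) for v in vals])
                i += 1
            break
        i += 1
    if not rows:
        raise ParseError(f"{path}: no letter-probability matrix block found")
    if w is not None and len(rows) != w:
        raise ParseError(f"{path}: matrix block has {len(rows)} rows but header says w= {w}")
    probs = np.array(rows).T  # rows are positions in MEME; we store (4, m)
    return ProbabilityMatrix(_normalize_columns(probs, str(path)), background)


def _read_pm_tsv(path: Path, text: str) -> ProbabilityMatrix:
    rows: dict[str, list[float]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].lower() == "pos":
            continue
        label = fields[0].upper()
        if label not in BASES:
            raise ParseError(f"{path}:{lineno}: unexpected row label {fields[0]!r}")
        rows[label] = [float(v) for v in fields[1:]]
    missing = [b for b in BASES if b not in rows]
    if missing:
        raise ParseError(f"{path}: missing rows for bases {missing}")
    probs = np.array([rows[b] for b in BASES])
    return ProbabilityMatrix(_normalize_columns(probs, str(path)))


def pm_display_percent(pm: ProbabilityMatrix) -> np.ndarray:
    """Display-only integer percentages (probability x 100, rounded)."""
    return np.rint(pm.probs * 100).astype(int)


# ---------------------------------------------------------------------------
# results + run metadata

def write_results_tsv(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, sep="\t", index=False)


def write_table_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


@dataclass
class RunMetadata:
    """Everything needed to reproduce a run bitwise."""

    command: str
    config: dict
    base_seed: int | None
    replicate_seeds: list[int] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat())

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")
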