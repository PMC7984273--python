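"""File formats: series CSV, run configuration, trace CSV, summary JSON.

Everything is plain text.  The trace CSV stores one retained iteration per
row with variable-length fields packed as ';'-separated lists ('|' between
segments) and a JSON metadata header comment, so a stored run can be
re-summarized without re-sampling.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .engine import PosteriorTrace
from .model import Hyperparams, TimeSeriesData

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "RunConfig",
    "save_trace",
    "load_trace",
    "save_json",
]


# ---------------------------------------------------------------------------
# series I/O


def read_timeseries(path) -> TimeSeriesData:
    """Read a single-column numeric CSV or a two-column (time, value) CSV.

    A header row is auto-detected; with a time column present, even spacing
    is enforced to a relative tolerance of 1e-6 and the sampling period is
    kept as metadata.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with path.open() as fh:
        lines = [(i + 1, ln.strip()) for i, ln in enumerate(fh) if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    start = 0
    try:
        [float(tok) for tok in lines[0][1].split(",")]
    except ValueError:
        start = 1  # header row
    for lineno, ln in lines[start:]:
        toks = ln.split(",")
        try:
            row = [float(tok) for tok in toks]
        except ValueError:
            raise ValueError(f"{path}: non-numeric value on line {lineno}") from None
        if len(row) not in (1, 2):
            raise ValueError(f"{path}: expected 1 or 2 columns, got {len(row)} on line {lineno}")
        rows.append(row)
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError(f"{path}: inconsistent column counts")
    if len(rows) < 4:
        raise ValueError(f"{path}: need at least 4 data points, found {len(rows)}")
    arr = np.asarray(rows, dtype=float)
    if ncol == 1:
        return TimeSeriesData(arr[:, 0])
    tcol, vals = arr[:, 0], arr[:, 1]
    steps = np.diff(tcol)
    if np.any(steps <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    dt = float(np.median(steps))
    if np.max(np.abs(steps - dt)) > 1e-6 * max(abs(dt), 1.0):
        raise ValueError(f"{path}: time column is not evenly spaced")
    return TimeSeriesData(vals, dt=dt)


def write_timeseries(path, data: TimeSeriesData, with_time: bool = False) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if with_time:
            fh.write("t,y\n")
            dt = data.dt if data.dt is not None else 1.0
            for i, v in enumerate(data.values, start=1):
                fh.write(f"{i * dt:.10g},{v:.12g}\n")
        else:
            fh.write("y\n")
            for v in data.values:
                fh.write(f"{v:.12g}\n")


# ---------------------------------------------------------------------------
# run configuration


_HP_FIELDS = {f.name for f in dataclasses.fields(Hyperparams)}


@dataclass
class RunConfig:
    """Flat, JSON-serializable bundle of sampler settings and run protocol."""

    hp: Hyperparams = dataclasses.field(default_factory=Hyperparams)
    n_iter: int = 20000
    burn_in: int = 5000
    thin: int = 1
    input: str | None = None
    outdir: str | None = None

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self.hp)
        out.update(n_iter=self.n_iter, burn_in=self.burn_in, thin=self.thin,
                   input=self.input, outdir=self.outdir)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        own = {"n_iter", "burn_in", "thin", "input", "outdir"}
        unknown = set(d) - _HP_FIELDS - own
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        hp = Hyperparams(**{k: v for k, v in d.items() if k in _HP_FIELDS})
        kw = {k: d[k] for k in own if k in d}
        return cls(hp=hp, **kw)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with Path(path).open() as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with Path(path).open("w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# trace I/O


def _fmt(values) -> str:
    return ";".join(f"{float(v):.12g}" for v in np.atleast_1d(values)) if np.size(values) else ""


def save_trace(trace: PosteriorTrace, path) -> None:
    meta = {
        "n": trace.n,
        "n_iter": trace.n_iter,
        "burn_in": trace.burn_in,
        "thin": trace.thin,
        "hp": dataclasses.asdict(trace.hp),
        "acceptance": trace.acceptance,
    }
    with Path(path).open("w") as fh:
        fh.write("# autonom-trace " + json.dumps(meta) + "\n")
        fh.write("iteration,k,loglik,s,m,omega,beta,sigma2\n")
        for i, (k, s, segs, ll) in enumerate(trace.snapshots):
            om = "|".join(_fmt(sg[0]) for sg in segs)
            be = "|".join(_fmt(sg[1]) for sg in segs)
            sg2 = _fmt([sg[2] for sg in segs])
            ms = _fmt([len(sg[0]) for sg in segs])
            fh.write(f"{i},{k},{ll:.12g},{_fmt(s)},{ms},{om},{be},{sg2}\n")


def load_trace(path) -> PosteriorTrace:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("# autonom-trace "):
            raise ValueError(f"{path}: not a trace file (missing metadata header)")
        meta = json.loads(header[len("# autonom-trace "):])
        colnames = fh.readline().strip().split(",")
        if colnames != ["iteration", "k", "loglik", "s", "m", "omega", "beta", "sigma2"]:
            raise ValueError(f"{path}: unexpected trace columns {colnames}")
        trace = PosteriorTrace(
            n=int(meta["n"]),
            hp=Hyperparams(**meta["hp"]),
            n_iter=int(meta["n_iter"]),
            burn_in=int(meta["burn_in"]),
            thin=int(meta["thin"]),
            acceptance=meta.get("acceptance", {}),
        )
        for lineno, ln in enumerate(fh, start=3):
            ln = ln.strip()
            if not ln:
                continue
            parts = ln.split(",")
            if len(parts) != 8:
                raise ValueError(f"{path}: malformed trace row on line {lineno}")
            _, k, ll, s, _, om, be, sg2 = parts
            k = int(k)
            s_arr = np.array([float(v) for v in s.split(";")] if s else [], dtype=float)
            omegas = [np.array([float(v) for v in blk.split(";")]) for blk in om.split("|")]
            betas = [np.array([float(v) for v in blk.split(";")]) for blk in be.split("|")]
            sigmas = [float(v) for v in sg2.split(";")]
            if not (len(omegas) == len(betas) == len(sigmas) == k + 1):
                raise ValueError(f"{path}: inconsistent segment counts on line {lineno}")
            trace.snapshots.append(
                (k, s_arr, list(zip(omegas, betas, sigmas)), float(ll))
            )
    return trace


def save_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
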