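"""Data input, preprocessing and serialization.

Reads cytometry samples from FCS 2.0/3.0/3.1 or delimited text, applies the
pipeline's three preprocessing steps, and serializes traces, merge results,
QC reports and configuration.

Preprocessing contract (order fixed, upstream compensation and nonlinear
transforms such as logicle/asinh are the caller's responsibility):

1. ``remove_extremes`` — drop events with a value above 0.999 times the
   per-marker pooled maximum or below 1.001 times the pooled minimum
   (saturated/railed events produce near-singular components);
2. ``percentile_scale`` — one affine map per marker from pooled data so the
   pooled 1% and 99% percentiles land at 0 and 1, identical across samples;
3. ``add_dither`` — Gaussian noise (sd 0.003) on a copy used only for dip
   tests, because the discreteness of digitized measurements disturbs them.

The FCS reader is minimal but self-contained: it parses the text segment
and a float/double/integer data segment; marker names come from $PnS with
fallback to $PnN.
"""

from __future__ import annotations

import json

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import SampleData

__all__ = [
    "ScalingTransform",
    "read_samples",
    "read_fcs",
    "remove_extremes",
    "percentile_scale",
    "add_dither",
    "export_results",
    "save_trace",
    "load_trace",
    "load_config",
    "save_config",
]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read an FCS 2.0/3.0/3.1 file; returns (events, marker names).

    Supports the common single-dataset layout with data type F (float32),
    D (float64) or I (unsigned integer with per-parameter bit widths that
    are multiples of 8) and list mode.
    """
    path = Path(path)
    raw = path.read_bytes()
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS"):
        raise ValueError(f"{path.name}: not an FCS file (header {version!r})")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:
        raise ValueError(f"{path.name}: malformed FCS header") from exc
    text = raw[text_start:text_end + 1].decode("latin-1")
    delim = text[0]
    fields = text[1:].split(delim)
    kv = {fields[i].strip(): fields[i + 1] for i in range(0, len(fields) - 1, 2)}

    n_par = int(kv["$PAR"])
    n_events = int(kv["$TOT"])
    dtype = kv["$DATATYPE"].strip().upper()
    byteord = kv.get("$BYTEORD", "1,2,3,4").strip()
    little = byteord.startswith("1")
    data_start = int(kv.get("$BEGINDATA", 0) or 0)
    data_end = int(kv.get("$ENDDATA", 0) or 0)
    if data_start == 0:
        data_start = int(raw[26:34])
        data_end = int(raw[34:42])
    buf = raw[data_start:data_end + 1]

    names = []
    for p in range(1, n_par + 1):
        name = kv.get(f"$P{p}S", "").strip() or kv.get(f"$P{p}N", f"P{p}").strip()
        names.append(name)

    order = "<" if little else ">"
    if dtype == "F":
        arr = np.frombuffer(buf[: 4 * n_par * n_events], dtype=f"{order}f4")
    elif dtype == "D":
        arr = np.frombuffer(buf[: 8 * n_par * n_events], dtype=f"{order}f8")
    elif dtype == "I":
        bits = {int(kv.get(f"$P{p}B", 32)) for p in range(1, n_par + 1)}
        if len(bits) != 1 or next(iter(bits)) not in (8, 16, 32):
            raise ValueError(f"{path.name}: unsupported integer widths {bits}")
        b = next(iter(bits)) // 8
        arr = np.frombuffer(buf[: b * n_par * n_events], dtype=f"{order}u{b}")
    else:
        raise ValueError(f"{path.name}: unsupported $DATATYPE {dtype!r}")
    events = np.asarray(arr, dtype=float).reshape(n_events, n_par)
    return events, names


def read_samples(paths: Sequence[str | Path], fmt: str = "auto",
                 markers: Optional[Sequence[str]] = None,
                 group_ids: Optional[Sequence[str]] = None) -> list[SampleData]:
    """Read samples from FCS or delimited-text files.

    Columns are aligned by marker name across samples; a requested marker
    missing from any sample raises an error naming the offending file.
    """
    samples = []
    for i, p in enumerate(paths):
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(str(p))
        kind = fmt
        if kind == "auto":
            kind = "fcs" if p.suffix.lower() == ".fcs" else "csv"
        if kind == "fcs":
            events, names = read_fcs(p)
            frame = pd.DataFrame(events, columns=names)
        else:
            sep = "\t" if p.suffix.lower() in (".tsv", ".txt") else ","
            frame = pd.read_csv(p, sep=sep)
        if markers is not None:
            missing = [m for m in markers if m not in frame.columns]
            if missing:
                raise ValueError(f"{p.name}: missing marker(s) {missing}")
            frame = frame[list(markers)]
        gid = group_ids[i] if group_ids is not None else None
        samples.append(SampleData(frame.to_numpy(dtype=float), sample_id=p.stem,
                                  group_id=gid, markers=list(frame.columns)))
    first = samples[0].markers
    for s in samples[1:]:
        if s.markers != first:
            if set(s.markers) == set(first):
                idx = [s.markers.index(m) for m in first]
                s.events = s.events[:, idx]
                s.markers = list(first)
            else:
                raise ValueError(
                    f"sample {s.sample_id!r}: marker set {s.markers} does not "
                    f"match {first}")
    return samples


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def remove_extremes(samples: Sequence[SampleData]) -> tuple[list[SampleData], dict[str, int]]:
    """Drop events with extreme values in at least one dimension.

    An event is removed when any coordinate exceeds 0.999 times the pooled
    per-marker maximum or falls below 1.001 times the pooled minimum — the
    rule as printed, so a positive maximum always removes the maximal event
    while a negative minimum removes nothing at the low end.
    """
    pooled = np.vstack([s.events for s in samples])
    hi = 0.999 * pooled.max(axis=0)
    lo = 1.001 * pooled.min(axis=0)
    out, removed = [], {}
    for s in samples:
        keep = np.all((s.events <= hi) & (s.events >= lo), axis=1)
        removed[s.sample_id] = int((~keep).sum())
        if keep.sum() == 0:
            raise ValueError(f"sample {s.sample_id!r}: all events removed")
        out.append(SampleData(s.events[keep], s.sample_id, s.group_id, s.markers))
    return out, removed


@dataclass
class ScalingTransform:
    """Per-marker affine map sending pooled q_0.01 to 0 and q_0.99 to 1."""

    offset: np.ndarray
    scale: np.ndarray

    def apply(self, events: np.ndarray) -> np.ndarray:
        return (events - self.offset) / self.scale

    def invert(self, scaled: np.ndarray) -> np.ndarray:
        return scaled * self.scale + self.offset

    def to_dict(self) -> dict:
        return {"offset": self.offset.tolist(), "scale": self.scale.tolist()}


def percentile_scale(samples: Sequence[SampleData]) -> tuple[list[SampleData], ScalingTransform]:
    """Scale all samples with one affine map per marker from pooled data.

    After scaling, the pooled 1% percentile is exactly 0 and the pooled
    99% percentile exactly 1 for every marker.
    """
    pooled = np.vstack([s.events for s in samples])
    q01 = np.quantile(pooled, 0.01, axis=0)
    q99 = np.quantile(pooled, 0.99, axis=0)
    if np.any(q99 <= q01):
        bad = np.flatnonzero(q99 <= q01)
        names = samples[0].markers
        label = [names[b] if names else str(b) for b in bad]
        raise ValueError(f"degenerate marker(s) {label}: q01 == q99")
    tf = ScalingTransform(offset=q01, scale=q99 - q01)
    out = [SampleData(tf.apply(s.events), s.sample_id, s.group_id, s.markers)
           for s in samples]
    return out, tf


def add_dither(samples: Sequence[SampleData], sd: float = 0.003,
               rng: Optional[np.random.Generator] = None) -> list[SampleData]:
    """Return a dithered copy (Gaussian noise, sd 0.003) for dip testing only.

    Digitized cytometry measurements produce striped patterns that disturb
    the dip test even when invisible; inference always uses the un-dithered
    data.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    return [SampleData(s.events + rng.normal(0.0, sd, size=s.events.shape)
                       if sd > 0 else s.events.copy(),
                       s.sample_id, s.group_id, s.markers)
            for s in samples]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_trace(trace, path: str | Path) -> None:
    """Serialize a trace to an HDF5 container (one group per block)."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("latent")
        g.create_dataset("theta", data=trace.theta)
        g.create_dataset("sigma_theta", data=trace.sigma_theta)
        g.create_dataset("psi", data=trace.psi)
        g.create_dataset("nu", data=trace.nu)
        g = f.create_group("samples")
        g.create_dataset("weights", data=trace.weights)
        g.create_dataset("active", data=trace.active)
        if trace.mu is not None:
            g.create_dataset("mu", data=trace.mu)
            g.create_dataset("sigma", data=trace.sigma)
        g = f.create_group("derived")
        for j, r in enumerate(trace.responsibilities):
            g.create_dataset(f"resp{j}", data=r)
        for j, p in enumerate(trace.ppc):
            g.create_dataset(f"ppc{j}", data=p)
        f.create_dataset("log_post", data=trace.log_post)
        f.attrs["sample_ids"] = json.dumps(list(trace.sample_ids))


def load_trace(path: str | Path):
    import h5py

    from .sampler import McmcTrace

    with h5py.File(path, "r") as f:
        sample_ids = json.loads(f.attrs["sample_ids"])
        J = len(sample_ids)
        mu = f["samples/mu"][()] if "mu" in f["samples"] else None
        sigma = f["samples/sigma"][()] if "sigma" in f["samples"] else None
        return McmcTrace(
            theta=f["latent/theta"][()],
            sigma_theta=f["latent/sigma_theta"][()],
            psi=f["latent/psi"][()],
            nu=f["latent/nu"][()],
            weights=f["samples/weights"][()],
            active=f["samples/active"][()],
            mu=mu, sigma=sigma,
            responsibilities=[f[f"derived/resp{j}"][()] for j in range(J)],
            ppc=[f[f"derived/ppc{j}"][()] for j in range(J)],
            log_post=f["log_post"][()],
            sample_ids=sample_ids,
        )


def export_results(trace, merge_result, qc_report, out_dir: str | Path,
                   data=None, config: Optional[dict] = None,
                   seed: Optional[int] = None) -> dict[str, Path]:
    """Write labels, soft weights, posterior summaries and reports.

    Per-event hard labels (0 = outlier, 1..K = components) and soft weights
    go to delimited text; posterior parameter summaries to the HDF5 trace
    container; merge and QC reports to JSON, along with the configuration
    and seed used.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for j, (sid, resp) in enumerate(zip(trace.sample_ids,
                                        trace.responsibilities)):
        hard = np.argmax(resp, axis=1)
        frame = pd.DataFrame(resp, columns=["outlier"] +
                             [f"comp{k}" for k in range(1, resp.shape[1])])
        frame.insert(0, "label", hard)
        frame.insert(0, "sample_id", sid)
        if merge_result is not None:
            pop = np.full(len(hard), -1)
            nz = hard > 0
            pop[nz] = merge_result.partition[hard[nz] - 1]
            frame.insert(2, "population", pop)
        rows.append(frame)
    labels = pd.concat(rows, ignore_index=True)
    paths["labels"] = out / "labels.tsv"
    labels.to_csv(paths["labels"], sep="\t", index=False, float_format="%.6g")

    paths["trace"] = out / "trace.h5"
    save_trace(trace, paths["trace"])

    if merge_result is not None:
        paths["merge"] = out / "merge.json"
        paths["merge"].write_text(json.dumps(merge_result.to_dict(), indent=1))
    if qc_report is not None:
        paths["qc"] = out / "qc.json"
        paths["qc"].write_text(json.dumps(qc_report.to_dict(), indent=1,
                                          default=str))
    run_info = {"seed": seed, "config": config}
    paths["run"] = out / "run.json"
    paths["run"].write_text(json.dumps(run_info, indent=1, default=str))
    return paths


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON configuration file."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(cfg: dict, path: str | Path) -> None:
    p = Path(path)
    if p.suffix.lower() == ".json":
        p.write_text(json.dumps(cfg, indent=1, default=str))
    else:
        p.write_text(yaml.safe_dump(cfg))
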