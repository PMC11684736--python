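"""High-throughput host x guest screening.

Every (host, guest) pair — including conformational ensembles supplied as
one file per conformation, the way implicit flexibility is handled — is
classified independently, so screening is embarrassingly parallel and the
result matrix is identical for any worker count. Per-pair failures (bad
geometry, radius underflow, optional timeout) are recorded as "error"
cells without aborting the rest of the screen.
"""

from __future__ import annotations

import json
import time
from concurrent.futures import ProcessPoolExecutor
from concurrent.futures import TimeoutError as FutureTimeoutError
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .geometry import SphereSet
from .mol_io import MolFileError
from .robustness import RobustnessClass, RobustnessParams, classify_pair

__all__ = [
    "ScreenResult",
    "EnsembleSummary",
    "screen",
    "summarize_ensemble",
    "read_screen_matrix",
]

_CLASSES = ("strong", "weak", "not", "error")


@dataclass(frozen=True)
class ScreenResult:
    """Robustness classes for all host x guest pairs, plus run metadata."""

    host_labels: tuple[str, ...]
    guest_labels: tuple[str, ...]
    classes: tuple[tuple[str, ...], ...]  # hosts x guests
    details: tuple[tuple[RobustnessClass | None, ...], ...] = ()
    errors: tuple[tuple[str | None, ...], ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.host_labels)) != len(self.host_labels):
            raise ValueError("host labels must be unique")
        if len(set(self.guest_labels)) != len(self.guest_labels):
            raise ValueError("guest labels must be unique")
        if len(self.classes) != len(self.host_labels) or any(
            len(row) != len(self.guest_labels) for row in self.classes
        ):
            raise ValueError("class matrix shape must be |hosts| x |guests|")
        for row in self.classes:
            for cell in row:
                if cell not in _CLASSES:
                    raise ValueError(f"invalid matrix cell {cell!r}")

    @property
    def n_pairs(self) -> int:
        return len(self.host_labels) * len(self.guest_labels)

    @property
    def n_errors(self) -> int:
        return sum(cell == "error" for row in self.classes for cell in row)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [list(r) for r in self.classes],
            index=list(self.host_labels),
            columns=list(self.guest_labels),
        )

    def details_payload(self) -> list[dict]:
        """JSON-serializable per-pair records (per-offset verdicts included)."""
        out = []
        for hi, hl in enumerate(self.host_labels):
            for gi, gl in enumerate(self.guest_labels):
                rec: dict = {"host": hl, "guest": gl, "class": self.classes[hi][gi]}
                detail = self.details[hi][gi] if self.details else None
                if detail is not None:
                    rec["offsets"] = [
                        {
                            "delta_r": off,
                            "outcome": v.outcome,
                            "diagnostic": v.diagnostic,
                            "witness": None
                            if v.witness is None
                            else {"t": v.witness.t.tolist(), "q": v.witness.q.tolist()},
                        }
                        for off, v in detail.per_offset
                    ]
                if self.errors and self.errors[hi][gi]:
                    rec["error"] = self.errors[hi][gi]
                out.append(rec)
        return out


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-label class counts and fractions along one axis of the matrix."""

    axis: str  # "hosts" | "guests"
    labels: tuple[str, ...]
    counts: tuple[dict, ...]  # per label: class -> count
    fractions: tuple[dict, ...]
    majority: tuple[tuple[str, float], ...]  # per label: (class, fraction)

    def frame(self) -> pd.DataFrame:
        rows = []
        for lbl, cnt, frac, (maj, mf) in zip(self.labels, self.counts, self.fractions, self.majority):
            row = {"label": lbl}
            row.update({f"n_{c}": cnt.get(c, 0) for c in _CLASSES})
            row.update({f"frac_{c}": frac.get(c, 0.0) for c in _CLASSES})
            row["majority"] = maj
            row["majority_fraction"] = mf
            rows.append(row)
        return pd.DataFrame(rows).set_index("label")


def _classify_cell(args):
    host, guest, params = args
    return classify_pair(host, guest, params)


def screen(
    hosts: list[tuple[str, SphereSet]],
    guests: list[tuple[str, SphereSet]],
    params: RobustnessParams | None = None,
    workers: int = 1,
    timeout: float | None = None,
) -> ScreenResult:
    """Classify every host x guest pair.

    Work is partitioned by pair index with no shared mutable state, so the
    matrix is identical for any ``workers`` count. ``timeout`` (seconds per
    pair, default none) marks pathological cells "error" instead of hanging
    a large screen; it requires a process pool (workers ignored = 1 path
    otherwise runs in-process).
    """
    if not hosts or not guests:
        raise ValueError("screen requires at least one host and one guest")
    params = params or RobustnessParams()
    tasks = [(h, g, params) for _, h in hosts for _, g in guests]
    n_g = len(guests)
    results: list[RobustnessClass | None] = [None] * len(tasks)
    errors: list[str | None] = [None] * len(tasks)
    t0 = time.perf_counter()
    wall: list[float] = [0.0] * len(tasks)

    if workers == 1 and timeout is None:
        for i, task in enumerate(tasks):
            tic = time.perf_counter()
            try:
                results[i] = _classify_cell(task)
            except Exception as exc:  # per-cell, never fatal
                errors[i] = f"{type(exc).__name__}: {exc}"
            wall[i] = time.perf_counter() - tic
    else:
        with ProcessPoolExecutor(max_workers=max(1, workers)) as pool:
            futures = [pool.submit(_classify_cell, task) for task in tasks]
            for i, fut in enumerate(futures):
                tic = time.perf_counter()
                try:
                    results[i] = fut.result(timeout=timeout)
                except FutureTimeoutError:
                    fut.cancel()
                    errors[i] = f"timeout: pair exceeded {timeout:g} s"
                except Exception as exc:
                    errors[i] = f"{type(exc).__name__}: {exc}"
                wall[i] = time.perf_counter() - tic

    classes = tuple(
        tuple(
            results[hi * n_g + gi].value if results[hi * n_g + gi] is not None else "error"
            for gi in range(n_g)
        )
        for hi in range(len(hosts))
    )
    details = tuple(
        tuple(results[hi * n_g + gi] for gi in range(n_g)) for hi in range(len(hosts))
    )
    errs = tuple(tuple(errors[hi * n_g + gi] for gi in range(n_g)) for hi in range(len(hosts)))
    meta = {
        "tool": "molcage",
        "version": __version__,
        "delta_r": params.delta_r,
        "offsets": list(params.offsets),
        "robust": params.delta_r > 0,
        "resolution": {
            "h": params.verify.h,
            "n_orientations": params.verify.n_orientations,
            "mode": params.verify.mode,
            "refine_levels": params.verify.refine_levels,
        },
        "workers": workers,
        "timeout": timeout,
        "wall_time_total_s": time.perf_counter() - t0,
        "wall_time_per_pair_s": wall,
    }
    return ScreenResult(
        host_labels=tuple(lbl for lbl, _ in hosts),
        guest_labels=tuple(lbl for lbl, _ in guests),
        classes=classes,
        details=details,
        errors=errs,
        metadata=meta,
    )


def summarize_ensemble(result: ScreenResult, axis: str = "hosts") -> EnsembleSummary:
    """Class counts and fractions per guest (axis='hosts': tally each guest's
    column over all host rows/conformations) or per host (axis='guests')."""
    if axis not in ("hosts", "guests"):
        raise ValueError("axis must be 'hosts' or 'guests'")
    frame = result.frame()
    if axis == "hosts":
        labels = result.guest_labels
        series = [frame[g] for g in labels]
    else:
        labels = result.host_labels
        series = [frame.loc[h] for h in labels]
    counts, fractions, majority = [], [], []
    for s in series:
        cnt = s.value_counts().to_dict()
        total = int(s.size)
        frac = {c: n / total for c, n in cnt.items()}
        maj = max(sorted(cnt), key=lambda c: cnt[c])
        counts.append(cnt)
        fractions.append(frac)
        majority.append((maj, cnt[maj] / total))
    return EnsembleSummary(
        axis=axis,
        labels=tuple(labels),
        counts=tuple(counts),
        fractions=tuple(fractions),
        majority=tuple(majority),
    )


def read_screen_matrix(path: str | Path) -> ScreenResult:
    """Read back a matrix written by :func:`molcage.mol_io.write_screen_matrix`
    (csv, tsv or json; the json variant restores metadata too)."""
    path = Path(path)
    suffix = path.suffix.lstrip(".").lower()
    if suffix == "json":
        payload = json.loads(path.read_text())
        hosts = tuple(payload["hosts"])
        guests = tuple(payload["guests"])
        matrix = payload["matrix"]
        classes = tuple(tuple(row) for row in matrix)
        _check_cells(classes, hosts, guests)
        return ScreenResult(hosts, guests, classes, metadata=payload.get("params", {}))
    sep = "\t" if suffix == "tsv" else ","
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    hosts = tuple(str(h) for h in frame.index)
    guests = tuple(str(g) for g in frame.columns)
    classes = tuple(tuple(str(v) for v in row) for row in frame.to_numpy())
    _check_cells(classes, hosts, guests)
    return ScreenResult(hosts, guests, classes)


def _check_cells(classes, hosts, guests) -> None:
    for hi, row in enumerate(classes):
        for gi, cell in enumerate(row):
            if cell not in _CLASSES:
                raise MolFileError(
                    f"invalid matrix cell {cell!r} at row {hosts[hi]!r}, column {guests[gi]!r}"
                )
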