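"""Data model and on-disk formats for behavioral sessions and spike tables.

A behavioral session is an ordered list of trials from a two-juice economic
choice task: on each trial the animal is offered ``qA`` drops of juice A
(the preferred juice) against ``qB`` drops of juice B, arranged left/right,
and indicates its choice by licking one of two spouts. Trials with exactly
one zero quantity are forced choices; licking the empty spout on a forced
choice is an error. Trials with no response are aborted and retained (with
``chosen_* = "none"``) so that trial-history regressors can be resolved.

All within-trial times are seconds from trial start. Sides are stored in
Euclidean coordinates (left/right); ipsi/contra is derived downstream from
the recording hemisphere and never stored.

On-disk layout for a session written to ``<stem>.csv``:

* ``<stem>.csv``        — one row per trial (including aborted trials)
* ``<stem>.licks.csv``  — lick events ``trial_index,side,time_s``
* ``<stem>.meta.json``  — ``mouse_id``, ``hemisphere_of_recording``, ``group``

Spike tables are event CSVs ``cell_id,trial_index,time_s`` with a sidecar
cell-metadata CSV ``cell_id,hemisphere``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

SIDES = ("left", "right")

TRIAL_COLUMNS = [
    "trial_index", "qA", "qB", "side_of_A", "stim", "chosen_juice",
    "chosen_side", "is_error", "offer_on_s", "go_s", "juice_on_s",
]
LICK_COLUMNS = ["trial_index", "side", "time_s"]
SPIKE_COLUMNS = ["cell_id", "trial_index", "time_s"]

#: spike timestamps must fall in this range (s from trial start)
SPIKE_TIME_RANGE = (-2.0, 10.0)


class ValidationError(ValueError):
    """A trial, session, or spike table violates a structural invariant."""


class ParseError(ValueError):
    """An on-disk file does not conform to the expected dialect."""


def opposite_side(side: str) -> str:
    return "right" if side == "left" else "left"


@dataclass(frozen=True)
class Trial:
    """One behavioral trial.

    ``chosen_juice``/``chosen_side`` are ``"none"`` on aborted trials and are
    mutually consistent with ``side_of_A`` otherwise (choosing juice A means
    licking A's spout — except that on forced-choice errors the animal licked
    the empty spout, which maps to the unoffered juice).
    """

    trial_index: int
    qA: int
    qB: int
    side_of_A: str
    stim: str  # "OFF" | "ON"
    chosen_juice: str  # "A" | "B" | "none"
    chosen_side: str  # "left" | "right" | "none"
    is_error: bool
    offer_on_s: float
    go_s: float
    juice_on_s: float  # NaN on aborted trials

    @property
    def forced(self) -> bool:
        return (self.qA == 0) != (self.qB == 0)

    @property
    def completed(self) -> bool:
        return self.chosen_juice != "none"

    @property
    def side_of_B(self) -> str:
        return opposite_side(self.side_of_A)

    def validate(self) -> None:
        ti = self.trial_index
        if ti < 0:
            raise ValidationError(f"trial {ti}: negative trial_index")
        if self.qA < 0 or self.qB < 0:
            raise ValidationError(f"trial {ti}: negative juice quantity")
        if self.qA == 0 and self.qB == 0:
            raise ValidationError(f"trial {ti}: both offers are zero")
        if self.side_of_A not in SIDES:
            raise ValidationError(f"trial {ti}: bad side_of_A {self.side_of_A!r}")
        if self.stim not in ("OFF", "ON"):
            raise ValidationError(f"trial {ti}: bad stim {self.stim!r}")
        if (self.chosen_juice == "none") != (self.chosen_side == "none"):
            raise ValidationError(
                f"trial {ti}: chosen_juice and chosen_side must both be 'none' "
                "on aborted trials"
            )
        if self.chosen_juice not in ("A", "B", "none"):
            raise ValidationError(f"trial {ti}: bad chosen_juice {self.chosen_juice!r}")
        if self.chosen_side not in ("left", "right", "none"):
            raise ValidationError(f"trial {ti}: bad chosen_side {self.chosen_side!r}")
        if self.is_error and not self.forced:
            raise ValidationError(f"trial {ti}: errors can occur only on forced choices")
        if self.completed:
            expected = self.side_of_A if self.chosen_juice == "A" else self.side_of_B
            if self.chosen_side != expected:
                raise ValidationError(
                    f"trial {ti}: chosen_side {self.chosen_side!r} inconsistent with "
                    f"chosen_juice {self.chosen_juice!r} and side_of_A {self.side_of_A!r}"
                )
        if self.go_s <= self.offer_on_s:
            raise ValidationError(f"trial {ti}: go_s must follow offer_on_s")


@dataclass
class Session:
    """Ordered trials plus lick events and metadata; the unit of fitting."""

    mouse_id: str
    trials: list[Trial]
    licks: list[tuple[int, str, float]] = field(default_factory=list)
    hemisphere_of_recording: str = "none"  # "left" | "right" | "none"
    group: str = "experimental"  # "experimental" | "control"

    def validate(self) -> None:
        prev = -1
        for tr in self.trials:
            tr.validate()
            if tr.trial_index <= prev:
                raise ValidationError(
                    f"trial_index not strictly increasing at {tr.trial_index}"
                )
            prev = tr.trial_index
        known = {tr.trial_index for tr in self.trials}
        for ti, side, t in self.licks:
            if ti not in known:
                raise ValidationError(f"lick references unknown trial_index {ti}")
            if side not in SIDES:
                raise ValidationError(f"lick on trial {ti} has bad side {side!r}")
        if self.hemisphere_of_recording not in ("left", "right", "none"):
            raise ValidationError(
                f"bad hemisphere_of_recording {self.hemisphere_of_recording!r}"
            )
        if self.group not in ("experimental", "control"):
            raise ValidationError(f"bad group {self.group!r}")

    def trial_by_index(self, trial_index: int) -> Trial:
        for tr in self.trials:
            if tr.trial_index == trial_index:
                return tr
        raise KeyError(trial_index)

    def lick_counts(self, t_start: float = 1.5, t_stop: float = 4.5) -> pd.Series:
        """Licks per trial in ``[t_start, t_stop)`` s from trial start.

        Every trial contributes a row (zero if it drew no licks).
        """
        counts = pd.Series(0, index=[tr.trial_index for tr in self.trials], dtype=int)
        for ti, _side, t in self.licks:
            if t_start <= t < t_stop:
                counts[ti] += 1
        return counts

    def stim_of_trial(self) -> pd.Series:
        return pd.Series(
            [tr.stim for tr in self.trials],
            index=[tr.trial_index for tr in self.trials],
        )


@dataclass
class SpikeTable:
    """Spike events ``(cell_id, trial_index, time_s)`` plus per-cell hemisphere.

    ``events`` is a DataFrame with columns ``cell_id, trial_index, time_s``;
    times are seconds relative to trial start.
    """

    events: pd.DataFrame
    hemispheres: dict[str, str]

    @property
    def cell_ids(self) -> list[str]:
        return sorted(self.hemispheres)

    def validate(self, known_trials: Iterable[int] | None = None) -> None:
        ev = self.events
        missing = [c for c in SPIKE_COLUMNS if c not in ev.columns]
        if missing:
            raise ValidationError(f"spike table missing columns {missing}")
        lo, hi = SPIKE_TIME_RANGE
        if len(ev) and not ((ev["time_s"] >= lo) & (ev["time_s"] <= hi)).all():
            raise ValidationError(f"spike times outside [{lo}, {hi}] s of trial start")
        for cid in ev["cell_id"].unique():
            if cid not in self.hemispheres:
                raise ValidationError(f"cell {cid!r} has no hemisphere metadata")
        for cid, hemi in self.hemispheres.items():
            if hemi not in SIDES:
                raise ValidationError(f"cell {cid!r} has bad hemisphere {hemi!r}")
        if known_trials is not None:
            known = set(known_trials)
            bad = set(ev["trial_index"].unique()) - known
            if bad:
                raise ValidationError(
                    f"spikes reference unknown trial_index {sorted(bad)[:5]}"
                )

    def times_by_cell_trial(self) -> dict[str, dict[int, np.ndarray]]:
        """Sorted spike-time arrays keyed by cell then trial."""
        out: dict[str, dict[int, np.ndarray]] = {c: {} for c in self.hemispheres}
        for (cid, ti), grp in self.events.groupby(["cell_id", "trial_index"], sort=True):
            out[cid][int(ti)] = np.sort(grp["time_s"].to_numpy(float))
        return out


# ---------------------------------------------------------------------------
# on-disk I/O


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    return path.with_suffix(".licks.csv"), path.with_suffix(".meta.json")


def write_session(session: Session, path: str | Path) -> None:
    """Write a session to ``path`` (trials CSV) plus lick and metadata sidecars."""
    session.validate()
    path = Path(path)
    rows = []
    for tr in session.trials:
        rows.append({
            "trial_index": tr.trial_index, "qA": tr.qA, "qB": tr.qB,
            "side_of_A": tr.side_of_A, "stim": tr.stim,
            "chosen_juice": tr.chosen_juice, "chosen_side": tr.chosen_side,
            "is_error": int(tr.is_error), "offer_on_s": tr.offer_on_s,
            "go_s": tr.go_s, "juice_on_s": tr.juice_on_s,
        })
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False, float_format="%.17g")
    licks_path, meta_path = _sidecar_paths(path)
    pd.DataFrame(session.licks, columns=LICK_COLUMNS).to_csv(
        licks_path, index=False, float_format="%.17g")
    meta = {
        "mouse_id": session.mouse_id,
        "hemisphere_of_recording": session.hemisphere_of_recording,
        "group": session.group,
    }
    meta_path.write_text(json.dumps(meta, indent=1))


def _parse_trial_row(i: int, row: pd.Series) -> Trial:
    try:
        juice_on = row["juice_on_s"]
        return Trial(
            trial_index=int(row["trial_index"]),
            qA=int(row["qA"]), qB=int(row["qB"]),
            side_of_A=str(row["side_of_A"]), stim=str(row["stim"]),
            chosen_juice=str(row["chosen_juice"]), chosen_side=str(row["chosen_side"]),
            is_error=bool(int(row["is_error"])),
            offer_on_s=float(row["offer_on_s"]), go_s=float(row["go_s"]),
            juice_on_s=float(juice_on) if pd.notna(juice_on) else math.nan,
        )
    except (TypeError, ValueError, KeyError) as exc:
        raise ParseError(f"malformed trial row {i}: {exc}") from exc


def read_session(path: str | Path) -> Session:
    """Read a session written by :func:`write_session`, validating invariants."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    trials = [_parse_trial_row(i, row) for i, row in df.iterrows()]

    licks_path, meta_path = _sidecar_paths(path)
    licks: list[tuple[int, str, float]] = []
    if licks_path.exists():
        ldf = pd.read_csv(licks_path, float_precision="round_trip")
        if len(ldf):
            licks = [
                (int(r["trial_index"]), str(r["side"]), float(r["time_s"]))
                for _, r in ldf.iterrows()
            ]
    meta = {"mouse_id": "unknown", "hemisphere_of_recording": "none",
            "group": "experimental"}
    if meta_path.exists():
        meta.update(json.loads(meta_path.read_text()))

    session = Session(
        mouse_id=meta["mouse_id"], trials=trials, licks=licks,
        hemisphere_of_recording=meta["hemisphere_of_recording"], group=meta["group"],
    )
    session.validate()
    return session


def write_spikes(spikes: SpikeTable, path: str | Path) -> None:
    path = Path(path)
    spikes.events[SPIKE_COLUMNS].to_csv(path, index=False, float_format="%.17g")
    cells = pd.DataFrame(
        sorted(spikes.hemispheres.items()), columns=["cell_id", "hemisphere"]
    )
    cells.to_csv(path.with_suffix(".cells.csv"), index=False)


def read_spikes(
    path: str | Path,
    cells_path: str | Path | None = None,
    known_trials: Iterable[int] | None = None,
) -> SpikeTable:
    """Read a spike event CSV with its cell-metadata sidecar.

    ``known_trials``, when given, triggers validation that every spike
    references an existing trial.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ev = pd.read_csv(path, float_precision="round_trip")
    if len(ev) == 0:
        ev = pd.DataFrame(columns=SPIKE_COLUMNS)
    missing = [c for c in SPIKE_COLUMNS if c not in ev.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    cells_path = Path(cells_path) if cells_path else path.with_suffix(".cells.csv")
    hemispheres: dict[str, str] = {}
    if cells_path.exists():
        cdf = pd.read_csv(cells_path)
        hemispheres = dict(zip(cdf["cell_id"].astype(str), cdf["hemisphere"].astype(str)))
    ev = ev.astype({"cell_id": str, "trial_index": int, "time_s": float})
    table = SpikeTable(events=ev, hemispheres=hemispheres)
    table.validate(known_trials=known_trials)
    return table
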