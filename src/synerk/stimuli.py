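"""Stimulation protocols: timed clamp windows for calcium, cAMP and Giβγ.

A protocol is pure data — a list of injections, each holding one input
species at a target free concentration for a window (the clamp realises the
stated peak regardless of the network's clearance; release hands the species
back to pumps/PDEs/buffers).  100 Hz trains are represented as one fused
clamp window per 1 s train, because the 10 ms inter-pulse gaps are far below
the clearance timescale.  File-based protocols replay a (time, species,
value) series as a piecewise-constant forcing input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical input names -> aliases accepted when resolving against a network
INPUT_ALIASES: dict[str, tuple[str, ...]] = {
    "calcium": ("calcium", "Ca", "ca"),
    "cAMP": ("cAMP", "camp", "camp_nM"),
    "Gbg": ("Gbg", "Gibg", "Gibetagamma", "GiBetaGamma"),
}

#: intertrain intervals (s) used by the L-LTP induction protocols
LLTP_ITIS: tuple[int, ...] = (3, 20, 40, 80, 300)


class ProtocolError(ValueError):
    pass


def canonical_input(name: str) -> str:
    for canon, aliases in INPUT_ALIASES.items():
        if name == canon or name in aliases:
            return canon
    raise ProtocolError(
        f"unknown input species {name!r}; valid inputs: {sorted(INPUT_ALIASES)}"
    )


def resolve_input_species(net, name: str) -> str:
    """Map a protocol input name onto the species name the network declares."""
    canon = canonical_input(name)
    declared = set(net.species_names)
    for alias in (canon, *INPUT_ALIASES[canon]):
        if alias in declared:
            return alias
    raise ProtocolError(
        f"network declares none of the aliases for input {canon!r}: "
        f"{INPUT_ALIASES[canon]}"
    )


@dataclass(frozen=True)
class Injection:
    species: str       # canonical input name
    onset: float       # s
    duration: float    # s
    target_peak: float  # nM held during the window

    def __post_init__(self) -> None:
        canonical_input(self.species)
        if self.onset < 0 or self.duration < 0:
            raise ProtocolError("injection onset/duration must be >= 0")
        if self.target_peak <= 0:
            raise ProtocolError("target_peak must be > 0 nM")


@dataclass(frozen=True)
class TrainSpec:
    frequency: float = 100.0   # Hz within a train
    pulses_per_train: int = 100
    n_trains: int = 4
    iti: float = 3.0           # s between trains


@dataclass(frozen=True)
class Protocol:
    """A schedule of clamp windows, or a file-based forcing series."""

    name: str = "protocol"
    injections: tuple[Injection, ...] = ()
    trains: TrainSpec | None = None
    source: str = "synthetic"  # or "file"
    # forcing series (file protocols): sample times plus one value row per time
    series_times: tuple[float, ...] = ()
    series_values: Mapping[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        onsets = [inj.onset for inj in self.injections]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ProtocolError("injection onsets must be non-decreasing")
        if self.source not in ("synthetic", "file"):
            raise ProtocolError(f"unknown protocol source {self.source!r}")
        if self.series_times:
            t = np.asarray(self.series_times)
            if np.any(np.diff(t) <= 0):
                raise ProtocolError("forcing-series times must be strictly increasing")

    # -- bookkeeping -----------------------------------------------------

    @property
    def input_species(self) -> tuple[str, ...]:
        names = {inj.species for inj in self.injections}
        names.update(canonical_input(s) for s in self.series_values)
        return tuple(sorted(names))

    def injected_exposure(self, species: str) -> float:
        """Clamp exposure in nM·s — linear in pulse count and per-pulse peak."""
        canon = canonical_input(species)
        total = sum(
            inj.target_peak * inj.duration
            for inj in self.injections
            if inj.species == canon
        )
        if self.series_times:
            t = np.asarray(self.series_times)
            for nm, vals in self.series_values.items():
                if canonical_input(nm) == canon:
                    total += float(np.sum(np.asarray(vals[:-1]) * np.diff(t)))
        return total

    @property
    def span(self) -> float:
        """Time of the last forced moment (s)."""
        t = 0.0
        for inj in self.injections:
            t = max(t, inj.onset + inj.duration)
        if self.series_times:
            t = max(t, self.series_times[-1])
        return t

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {
            "name": self.name,
            "source": self.source,
            "injections": [
                {"species": i.species, "onset": i.onset,
                 "duration": i.duration, "target_peak": i.target_peak}
                for i in self.injections
            ],
        }
        if self.trains is not None:
            out["trains"] = {
                "frequency": self.trains.frequency,
                "pulses_per_train": self.trains.pulses_per_train,
                "n_trains": self.trains.n_trains,
                "iti": self.trains.iti,
            }
        if self.series_times:
            out["series_times"] = list(self.series_times)
            out["series_values"] = {k: list(v) for k, v in self.series_values.items()}
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "Protocol":
        trains = d.get("trains")
        return cls(
            name=str(d.get("name", "protocol")),
            source=str(d.get("source", "synthetic")),
            injections=tuple(
                Injection(i["species"], float(i["onset"]), float(i["duration"]),
                          float(i["target_peak"]))
                for i in d.get("injections", ())
            ),
            trains=TrainSpec(**trains) if trains else None,
            series_times=tuple(float(t) for t in d.get("series_times", ())),
            series_values={
                k: tuple(float(x) for x in v)
                for k, v in d.get("series_values", {}).items()
            },
        )

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Protocol":
        import json

        return cls.from_dict(json.loads(Path(path).read_text()))

    def shifted(self, dt: float) -> "Protocol":
        """The same schedule delayed by ``dt`` seconds (pre-stimulus baseline)."""
        return replace(
            self,
            injections=tuple(
                replace(inj, onset=inj.onset + dt) for inj in self.injections
            ),
            series_times=tuple(t + dt for t in self.series_times),
        )

    def merged_with(self, other: "Protocol", name: str | None = None) -> "Protocol":
        """Co-schedule two protocols (their injections interleaved by onset)."""
        if self.series_times and other.series_times:
            raise ProtocolError("cannot merge two file-based protocols")
        inj = tuple(sorted(
            (*self.injections, *other.injections), key=lambda i: i.onset
        ))
        return replace(
            self,
            name=name or f"{self.name}+{other.name}",
            injections=inj,
            series_times=self.series_times or other.series_times,
            series_values=dict(self.series_values) | dict(other.series_values),
        )

    # -- clamp schedule for the solvers ----------------------------------

    def clamp_segments(self, t_end: float) -> list[tuple[float, float, dict[str, float]]]:
        """Piecewise-constant clamp plan: (t0, t1, {canonical input: nM}).

        Overlapping windows for the same species clamp at the larger target.
        Segments tile [0, t_end] exactly.
        """
        events = {0.0, float(t_end)}
        for inj in self.injections:
            if inj.duration <= 0 or inj.onset >= t_end:
                continue
            events.add(inj.onset)
            events.add(min(inj.onset + inj.duration, t_end))
        for t in self.series_times:
            if 0.0 <= t < t_end:
                events.add(float(t))
        # end of forcing series releases the clamp
        if self.series_times and self.series_times[-1] < t_end:
            events.add(float(self.series_times[-1]))
        cuts = sorted(e for e in events if 0.0 <= e <= t_end)
        segments: list[tuple[float, float, dict[str, float]]] = []
        st = np.asarray(self.series_times) if self.series_times else None
        for t0, t1 in zip(cuts, cuts[1:]):
            mid = 0.5 * (t0 + t1)
            clamp: dict[str, float] = {}
            for inj in self.injections:
                if inj.duration > 0 and inj.onset <= mid < inj.onset + inj.duration:
                    prev = clamp.get(inj.species, 0.0)
                    clamp[inj.species] = max(prev, inj.target_peak)
            if st is not None and st[0] <= mid < st[-1]:
                k = int(np.searchsorted(st, mid, side="right") - 1)
                for nm, vals in self.series_values.items():
                    clamp[canonical_input(nm)] = float(vals[k])
            segments.append((t0, t1, clamp))
        return segments


EMPTY_PROTOCOL = Protocol(name="unstimulated")


# ---------------------------------------------------------------------------
# constructors


def single_pulse_protocol(
    species: str, amplitude: float, duration: float, onset: float = 0.0
) -> Protocol:
    """One clamp window holding ``species`` at ``amplitude`` nM for ``duration`` s."""
    canon = canonical_input(species)
    if amplitude <= 0:
        raise ProtocolError(f"amplitude must be > 0 nM, got {amplitude}")
    if duration < 0:
        raise ProtocolError(f"duration must be >= 0 s, got {duration}")
    if duration == 0:
        return Protocol(name=f"{canon}_pulse_empty")
    return Protocol(
        name=f"{canon}_{amplitude:g}nM_{duration:g}s",
        injections=(Injection(canon, onset, duration, amplitude),),
    )


def train_protocol(
    inputs: Mapping[str, float],
    n_trains: int,
    iti: float,
    train_duration: float = 1.0,
    frequency: float = 100.0,
    pulses_per_train: int = 100,
    onset: float = 0.0,
    name: str | None = None,
) -> Protocol:
    """``n_trains`` fused 100 Hz trains; train k starts at onset + k·(dur + iti)."""
    injections = []
    for k in range(n_trains):
        t0 = onset + k * (train_duration + iti)
        for sp, peak in sorted(inputs.items()):
            injections.append(Injection(canonical_input(sp), t0, train_duration, peak))
    injections.sort(key=lambda i: i.onset)
    return Protocol(
        name=name or f"train_x{n_trains}_iti{iti:g}",
        injections=tuple(injections),
        trains=TrainSpec(frequency, pulses_per_train, n_trains, iti),
    )


def lltp_protocol(iti: float, inputs: Mapping[str, float], onset: float = 0.0) -> Protocol:
    """L-LTP induction: four 1 s trains of 100 Hz separated by ``iti`` seconds.

    ``inputs`` maps input species to the within-train free peak (nM),
    e.g. {"calcium": 1000} for 1 µM calcium pulses.
    """
    if iti not in LLTP_ITIS:
        raise ProtocolError(
            f"invalid intertrain interval {iti}; valid values: {list(LLTP_ITIS)}"
        )
    return train_protocol(
        inputs, n_trains=4, iti=float(iti), onset=onset,
        name=f"lltp_iti{iti:g}",
    )


def validation_protocols(onset: float = 0.0) -> dict[str, Protocol]:
    """The two experiment-replication protocols.

    ``rasgtp_uncaging``: a single 60 s plateau of 0.5 µM calcium (stands in
    for 0.5 Hz glutamate uncaging in zero extracellular Mg).
    ``llp_2x100Hz``: two 1 s, 100 Hz trains 20 s apart delivering 5 µM
    calcium, 1 µM cAMP and 0.1 µM Giβγ.
    """
    return {
        "rasgtp_uncaging": single_pulse_protocol("calcium", 500.0, 60.0, onset=onset),
        "llp_2x100Hz": train_protocol(
            {"calcium": 5000.0, "cAMP": 1000.0, "Gbg": 100.0},
            n_trains=2, iti=20.0, onset=onset, name="llp_2x100Hz",
        ),
    }


def load_timeseries_protocol(file: str | Path | pd.DataFrame, name: str | None = None) -> Protocol:
    """Forcing-input protocol from a CSV with columns time_s, species, value_nM."""
    df = file if isinstance(file, pd.DataFrame) else pd.read_csv(file)
    for col in ("time_s", "species", "value_nM"):
        if col not in df.columns:
            raise ProtocolError(f"time-series file lacks column {col!r}")
    times = np.unique(df["time_s"].to_numpy(float))
    values: dict[str, np.ndarray] = {}
    for sp, grp in df.groupby("species"):
        canon = canonical_input(str(sp))
        t = grp["time_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ProtocolError(f"non-monotone times for species {sp!r}")
        v = np.interp(times, t, grp["value_nM"].to_numpy(float))
        values[canon] = v
    if np.allclose([v for vv in values.values() for v in vv], 0.0):
        return Protocol(name=name or "unstimulated_series")
    return Protocol(
        name=name or (str(file) if not isinstance(file, pd.DataFrame) else "series"),
        source="file",
        series_times=tuple(float(t) for t in times),
        series_values={k: tuple(map(float, v)) for k, v in values.items()},
    )
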