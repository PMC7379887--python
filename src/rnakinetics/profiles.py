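"""Replicated expression profiles and their tab-separated representations.

An :class:`ExpressionProfile` holds, per time point, the across-replicate
mean and standard deviation of premature RNA, mature RNA and (in the
nascent-RNA mode) the observed synthesis rate.  Two TSV dialects are
supported:

* **replicate (long)**: columns ``time  species  replicate  value`` with
  species in {premature, mature, synthesis}; the reader aggregates to
  means/sds.
* **aggregated (wide)**: columns ``time  premature_mean  premature_sd
  mature_mean  mature_sd [synthesis_mean  synthesis_sd]``; the replicate
  count is carried in a ``# n_replicates=N`` comment line.

Comment lines start with ``#``; fields are tab-separated with ``.`` decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = ["ExpressionProfile", "read_profile", "write_profile"]

_SPECIES = ("premature", "mature", "synthesis")


@dataclass(frozen=True)
class ExpressionProfile:
    """Replicated observations of the RNA species of one gene over time."""

    times: np.ndarray
    premature_mean: np.ndarray
    premature_sd: np.ndarray
    mature_mean: np.ndarray
    mature_sd: np.ndarray
    synthesis_mean: np.ndarray | None = None
    synthesis_sd: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        n = self.times.shape[0]
        if n == 0:
            raise DomainError("profile requires at least one time point")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise DomainError("profile times must be strictly increasing")
        for name in (
            "premature_mean", "premature_sd", "mature_mean", "mature_sd",
            "synthesis_mean", "synthesis_sd",
        ):
            val = getattr(self, name)
            if val is None:
                continue
            arr = np.asarray(val, dtype=float)
            if arr.shape != (n,):
                raise DomainError(f"profile field {name} must have length {n}")
            if name.endswith("_sd") and np.any(arr < 0):
                raise DomainError(f"{name} must be non-negative")
            object.__setattr__(self, name, arr)
        if (self.synthesis_mean is None) != (self.synthesis_sd is None):
            raise DomainError("synthesis_mean and synthesis_sd must come together")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")

    @property
    def has_synthesis(self) -> bool:
        return self.synthesis_mean is not None

    @property
    def n_times(self) -> int:
        return int(self.times.shape[0])

    @property
    def n_observations(self) -> int:
        """Number of observed means entering a fit objective."""
        return self.n_times * (3 if self.has_synthesis else 2)

    def species(self) -> tuple[str, ...]:
        return _SPECIES if self.has_synthesis else _SPECIES[:2]

    def mean(self, species: str) -> np.ndarray:
        return getattr(self, f"{species}_mean")

    def sd(self, species: str) -> np.ndarray:
        return getattr(self, f"{species}_sd")

    @classmethod
    def from_replicates(cls, df: pd.DataFrame) -> "ExpressionProfile":
        """Aggregate a long replicate table (time, species, replicate, value).

        Means and sds are computed across replicates (ddof=1); the replicate
        count is the maximum per-point count.
        """
        required = {"time", "species", "replicate", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigurationError(f"replicate table missing columns {sorted(missing)}")
        bad = set(df["species"].unique()) - set(_SPECIES)
        if bad:
            raise ConfigurationError(
                f"unknown species {sorted(bad)}; expected {list(_SPECIES)}"
            )
        times = np.sort(df["time"].unique())
        fields: dict[str, np.ndarray | None] = {}
        n_rep = 1
        for sp in _SPECIES:
            sub = df[df["species"] == sp]
            if sub.empty:
                fields[f"{sp}_mean"] = None
                fields[f"{sp}_sd"] = None
                continue
            g = sub.groupby("time")["value"]
            if not np.array_equal(np.sort(sub["time"].unique()), times):
                raise ConfigurationError(f"species {sp} does not cover all time points")
            counts = g.count()
            n_rep = max(n_rep, int(counts.max()))
            means = g.mean().reindex(times).to_numpy()
            sds = g.std(ddof=1).reindex(times).fillna(0.0).to_numpy()
            fields[f"{sp}_mean"] = means
            fields[f"{sp}_sd"] = sds
        if fields["premature_mean"] is None or fields["mature_mean"] is None:
            raise ConfigurationError("profile requires premature and mature species")
        return cls(times=times, n_replicates=n_rep, **fields)


def _parse_float(token: str, path, lineno: int, col: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ConfigurationError(
            f"{path}:{lineno}: column {col!r}: cannot parse {token!r} as a number"
        ) from None


def read_profile(path) -> ExpressionProfile:
    """Read a profile TSV, auto-detecting the replicate or aggregated dialect."""
    rows: list[tuple[int, list[str]]] = []
    n_replicates = None
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if stripped.startswith("n_replicates"):
                    n_replicates = int(stripped.split("=")[1])
                continue
            if header is None:
                header = line.split("\t")
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ConfigurationError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            rows.append((lineno, fields))
    if header is None or not rows:
        raise ConfigurationError(f"{path}: no data rows found")

    if "species" in header and "replicate" in header:
        idx = {c: header.index(c) for c in ("time", "species", "replicate", "value")}
        records = []
        for lineno, fields in rows:
            sp = fields[idx["species"]]
            if sp not in _SPECIES:
                raise ConfigurationError(
                    f"{path}:{lineno}: unknown species {sp!r}; expected {list(_SPECIES)}"
                )
            records.append(
                {
                    "time": _parse_float(fields[idx["time"]], path, lineno, "time"),
                    "species": sp,
                    "replicate": fields[idx["replicate"]],
                    "value": _parse_float(fields[idx["value"]], path, lineno, "value"),
                }
            )
        return ExpressionProfile.from_replicates(pd.DataFrame.from_records(records))

    required = ["time", "premature_mean", "premature_sd", "mature_mean", "mature_sd"]
    missing = [c for c in required if c not in header]
    if missing:
        raise ConfigurationError(f"{path}: missing columns {missing}")
    cols: dict[str, list[float]] = {c: [] for c in header}
    for lineno, fields in rows:
        for c, token in zip(header, fields):
            cols[c].append(_parse_float(token, path, lineno, c))
    has_synth = "synthesis_mean" in header and "synthesis_sd" in header
    return ExpressionProfile(
        times=np.array(cols["time"]),
        premature_mean=np.array(cols["premature_mean"]),
        premature_sd=np.array(cols["premature_sd"]),
        mature_mean=np.array(cols["mature_mean"]),
        mature_sd=np.array(cols["mature_sd"]),
        synthesis_mean=np.array(cols["synthesis_mean"]) if has_synth else None,
        synthesis_sd=np.array(cols["synthesis_sd"]) if has_synth else None,
        n_replicates=n_replicates or 1,
    )


def write_profile(profile: ExpressionProfile, path, header_lines: Sequence[str] = ()) -> None:
    """Write the aggregated (wide) dialect with fixed column order."""
    data = {"time": profile.times}
    for sp in profile.species():
        data[f"{sp}_mean"] = profile.mean(sp)
        data[f"{sp}_sd"] = profile.sd(sp)
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"# n_replicates={profile.n_replicates}\n")
        df.to_csv(fh, sep="\t", index=False)
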