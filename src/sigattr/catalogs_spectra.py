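"""Channel schemes, spectrum/signature/activity containers, and TSV I/O.

Matrices are exchanged as COSMIC-convention tab-separated files: the first
column holds mutation-type (or signature) row labels, remaining columns are
samples or signatures.  Rows are re-sorted into canonical channel order on
load, so files produced by different tools interoperate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from sigattr._channels import DBS78_LABELS, ID83_LABELS, SBS96_LABELS

__all__ = [
    "ChannelScheme",
    "Spectrum",
    "SpectrumSet",
    "SignatureCatalog",
    "Attribution",
    "get_scheme",
    "infer_scheme",
    "load_matrix_tsv",
    "write_matrix_tsv",
    "cosine_similarity",
]

#: Accepted names for the row-label column in TSV headers.
_LABEL_HEADER_ALIASES = {"mutationtype", "mutation type", "type", ""}


@dataclass(frozen=True)
class ChannelScheme:
    """An ordered set of mutation-type labels defining spectrum dimension."""

    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"duplicate labels in scheme {self.name!r}")

    @property
    def k(self) -> int:
        return len(self.labels)

    def index_of(self, labels: Sequence[str]) -> np.ndarray:
        """Positions of *labels* in canonical order; unknown labels raise."""
        lookup = {lab: i for i, lab in enumerate(self.labels)}
        unknown = [lab for lab in labels if lab not in lookup]
        if unknown:
            raise ValueError(
                f"labels not in scheme {self.name!r}: {sorted(unknown)!r}"
            )
        return np.array([lookup[lab] for lab in labels], dtype=np.intp)


SBS96 = ChannelScheme("SBS96", SBS96_LABELS)
DBS78 = ChannelScheme("DBS78", DBS78_LABELS)
ID83 = ChannelScheme("ID83", ID83_LABELS)

_SCHEMES: dict[str, ChannelScheme] = {s.name: s for s in (SBS96, DBS78, ID83)}


def get_scheme(name: str) -> ChannelScheme:
    """Return a registered channel scheme by name (SBS96, DBS78, ID83)."""
    try:
        return _SCHEMES[name]
    except KeyError:
        raise KeyError(
            f"unknown scheme {name!r}; known: {sorted(_SCHEMES)}"
        ) from None


def infer_scheme(labels: Sequence[str]) -> ChannelScheme:
    """Infer the channel scheme whose label set exactly matches *labels*."""
    label_set = set(labels)
    for scheme in _SCHEMES.values():
        if label_set == set(scheme.labels):
            return scheme
    raise ValueError(
        f"row labels match no known channel scheme "
        f"(got {len(label_set)} unique labels)"
    )


@dataclass(frozen=True)
class Spectrum:
    """Per-channel non-negative integer mutation counts for one sample."""

    sample_id: str
    scheme: ChannelScheme
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (self.scheme.k,):
            raise ValueError(
                f"counts shape {counts.shape} != ({self.scheme.k},)"
            )
        counts = _coerce_integer_counts(counts, context=self.sample_id)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SpectrumSet:
    """A collection of spectra sharing one channel scheme (k x n counts)."""

    scheme: ChannelScheme
    sample_ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        n = len(self.sample_ids)
        if counts.shape != (self.scheme.k, n):
            raise ValueError(
                f"counts shape {counts.shape} != ({self.scheme.k}, {n})"
            )
        counts = _coerce_integer_counts(counts, context="spectrum set")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return len(self.sample_ids)

    def __iter__(self) -> Iterator[Spectrum]:
        for j, sid in enumerate(self.sample_ids):
            yield Spectrum(sid, self.scheme, self.counts[:, j])

    def __getitem__(self, sample_id: str) -> Spectrum:
        j = self.sample_ids.index(sample_id)
        return Spectrum(sample_id, self.scheme, self.counts[:, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.copy(),
            index=pd.Index(self.scheme.labels, name="MutationType"),
            columns=list(self.sample_ids),
        )


@dataclass(frozen=True)
class SignatureCatalog:
    """k x g matrix of signature probability vectors (columns sum to 1)."""

    scheme: ChannelScheme
    names: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    #: column sums may deviate from 1 by at most this much before rejection
    COLUMN_SUM_TOL = 1e-3

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        g = len(self.names)
        if mat.shape != (self.scheme.k, g):
            raise ValueError(f"matrix shape {mat.shape} != ({self.scheme.k}, {g})")
        if len(set(self.names)) != g:
            raise ValueError("duplicate signature names")
        if (mat < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = mat.sum(axis=0)
        bad = np.abs(sums - 1.0) > self.COLUMN_SUM_TOL
        if bad.any():
            offenders = {
                self.names[j]: float(sums[j]) for j in np.flatnonzero(bad)
            }
            raise ValueError(
                f"signature columns do not sum to 1: {offenders!r}"
            )
        # exact renormalization so downstream reconstructions are consistent
        object.__setattr__(self, "matrix", mat / sums)

    @property
    def g(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown signature {name!r}") from None
        return self.matrix[:, j]

    def restrict(self, names: Sequence[str]) -> "SignatureCatalog":
        """Sub-catalog with the given signatures, in the given order."""
        cols = [self.names.index(n) if n in self.names else -1 for n in names]
        missing = [n for n, c in zip(names, cols) if c < 0]
        if missing:
            raise KeyError(f"unknown signatures: {missing!r}")
        return SignatureCatalog(
            self.scheme, tuple(names), self.matrix[:, cols]
        )

    def drop(self, name: str) -> "SignatureCatalog":
        return self.restrict([n for n in self.names if n != name])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.copy(),
            index=pd.Index(self.scheme.labels, name="MutationType"),
            columns=list(self.names),
        )


@dataclass(frozen=True)
class Attribution:
    """Mapping signature name -> positive activity (attributed mutations).

    Zero-activity signatures are absent from the mapping by construction.
    """

    sample_id: str
    activities: Mapping[str, float]

    def __post_init__(self) -> None:
        cleaned = {}
        for name, act in self.activities.items():
            act = float(act)
            if act < 0:
                raise ValueError(f"negative activity for {name!r}: {act}")
            if act > 0:
                cleaned[name] = act
        object.__setattr__(self, "activities", cleaned)

    @property
    def signatures(self) -> frozenset[str]:
        return frozenset(self.activities)

    @property
    def total_activity(self) -> float:
        return float(sum(self.activities.values()))

    def __len__(self) -> int:
        return len(self.activities)

    def as_vector(self, universe: Sequence[str]) -> np.ndarray:
        """Dense activity vector over *universe*, zeros where absent."""
        extra = set(self.activities) - set(universe)
        if extra:
            raise ValueError(f"activities outside universe: {sorted(extra)!r}")
        return np.array([self.activities.get(n, 0.0) for n in universe])


def _coerce_integer_counts(values: np.ndarray, context: str) -> np.ndarray:
    """Validate non-negative near-integer counts, returning int64 counts."""
    values = np.asarray(values)
    if (np.asarray(values, dtype=float) < 0).any():
        raise ValueError(f"negative counts in {context}")
    if np.issubdtype(values.dtype, np.integer):
        return values.astype(np.int64)
    rounded = np.rint(np.asarray(values, dtype=float))
    off = np.abs(values - rounded) > 1e-6
    if off.any():
        raise ValueError(
            f"non-integer counts in {context}: "
            f"{np.asarray(values)[off][:5].tolist()!r}..."
        )
    return rounded.astype(np.int64)


def _read_label_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    first = str(df.columns[0])
    if first.strip().lower() not in _LABEL_HEADER_ALIASES and not first.startswith(
        "Unnamed"
    ):
        # Some writers use an arbitrary label-column name; accept it only if
        # the column is non-numeric (it must hold labels, not data).
        try:
            pd.to_numeric(df.iloc[:, 0])
        except (ValueError, TypeError):
            pass
        else:
            raise ValueError(
                f"{path}: first column {first!r} looks numeric; expected "
                "mutation-type row labels"
            )
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicated row labels {dupes!r}")
    return df


def load_matrix_tsv(
    path: str | Path,
    role: str,
    scheme: ChannelScheme | None = None,
):
    """Load a COSMIC-style TSV matrix.

    Parameters
    ----------
    path:
        Tab-separated file; first column row labels, remaining columns
        samples or signatures.
    role:
        ``"spectra"`` -> :class:`SpectrumSet`; ``"signatures"`` ->
        :class:`SignatureCatalog`; ``"activities"`` -> a signatures x
        samples :class:`pandas.DataFrame` (no scheme applies).
    scheme:
        Channel scheme to validate against; inferred from the row labels
        when omitted (spectra/signatures only).
    """
    if role not in {"spectra", "signatures", "activities"}:
        raise ValueError(f"unknown role {role!r}")
    df = _read_label_frame(path)
    values = df.to_numpy()
    if not np.issubdtype(np.asarray(values).dtype, np.number):
        try:
            values = df.astype(float).to_numpy()
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric matrix values: {exc}") from exc

    if role == "activities":
        if (values < 0).any():
            raise ValueError(f"{path}: negative activities")
        out = df.astype(float)
        out.index.name = "Signature"
        return out

    labels = list(df.index)
    if scheme is None:
        scheme = infer_scheme(labels)
    present = set(labels)
    missing = [lab for lab in scheme.labels if lab not in present]
    unknown = [lab for lab in labels if lab not in set(scheme.labels)]
    if missing or unknown:
        raise ValueError(
            f"{path}: row labels do not match scheme {scheme.name}; "
            f"missing={missing[:5]!r} unknown={unknown[:5]!r}"
        )
    # canonical re-ordering regardless of input row order
    order = [labels.index(lab) for lab in scheme.labels]
    values = np.asarray(values, dtype=float)[order, :]

    if role == "spectra":
        if (values < 0).any():
            raise ValueError(f"{path}: negative spectrum counts")
        return SpectrumSet(scheme, tuple(df.columns.astype(str)), values)
    return SignatureCatalog(scheme, tuple(df.columns.astype(str)), values)


def write_matrix_tsv(obj, path: str | Path) -> None:
    """Write a SpectrumSet, SignatureCatalog, or activity DataFrame as TSV."""
    if isinstance(obj, (SpectrumSet, SignatureCatalog)):
        frame = obj.to_frame()
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    else:
        raise TypeError(f"cannot write {type(obj).__name__} as a matrix TSV")
    frame.to_csv(path, sep="\t", lineterminator="\n")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two non-negative vectors, in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), 0.0, 1.0))
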