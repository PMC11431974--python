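"""Reading and writing of ECG recordings, fiducial annotations and tables.

The recording dialect (``txt_matrix``) is a plain-text sample matrix:
``#key=value`` metadata lines, one header line of lead names, then one
delimited row of amplitudes per time step.  It is self-describing and
diff-friendly, mirroring the exported text files common to clinical
electrophysiology systems.  All amplitudes are held in millivolts in
memory; readers convert microvolts or raw ADC counts at ingest.

Sample indexing is 0-based everywhere; times derive as ``index / fs``.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: The 12 standard leads, in conventional order.
STANDARD_LEADS = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)
_CANONICAL = {name.lower(): name for name in STANDARD_LEADS}

#: Closed vocabulary of fiducial kinds.
FIDUCIAL_KINDS = ("R_PEAK", "T_END", "P_PEAK", "P_ONSET", "P_OFFSET")

#: Allowed annotation provenance values.  Override records win over
#: detected records sharing the same (lead, beat, kind) key.
PROVENANCES = ("detected", "override")


def canonical_lead(name: str) -> str:
    """Map a lead label to its canonical form (case-insensitive for the
    12 standard labels); unknown labels pass through with a warning."""
    key = name.strip().lower()
    if key in _CANONICAL:
        return _CANONICAL[key]
    warnings.warn(f"unknown lead label {name!r}; retained as-is", stacklevel=2)
    return name.strip()


@dataclass
class EcgRecording:
    """A multi-lead ECG sample matrix with acquisition metadata.

    Parameters
    ----------
    samples:
        Lead-major matrix of amplitudes in mV, shape ``(n_leads, n_samples)``.
    fs:
        Sampling rate in Hz (must be positive).
    lead_names:
        Ordered, unique lead labels.
    adc_bits, adc_range_mv:
        Optional digitiser metadata (e.g. 16 bits over a 10 mV span).
        When both are present, amplitudes must lie within ±range/2.
    source_id:
        Free-text identifier of the recording's origin.
    """

    samples: np.ndarray
    fs: float
    lead_names: tuple[str, ...]
    adc_bits: int | None = None
    adc_range_mv: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_leads, n_samples)")
        self.lead_names = tuple(self.lead_names)
        if len(self.lead_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.lead_names)} lead names for "
                f"{self.samples.shape[0]} sample rows"
            )
        if len(set(n.lower() for n in self.lead_names)) != len(self.lead_names):
            raise ValueError("lead names must be unique")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.adc_bits is not None and self.adc_range_mv is not None:
            half = self.adc_range_mv / 2.0
            quantum = self.adc_range_mv / 2 ** self.adc_bits
            if self.samples.size and np.abs(self.samples).max() > half + quantum:
                raise ValueError(
                    "amplitudes exceed the declared ADC range of "
                    f"±{half} mV"
                )

    @property
    def n_leads(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def adc_quantum_mv(self) -> float | None:
        if self.adc_bits is None or self.adc_range_mv is None:
            return None
        return self.adc_range_mv / 2 ** self.adc_bits

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's samples; lookup is case-insensitive."""
        want = name.strip().lower()
        for i, label in enumerate(self.lead_names):
            if label.lower() == want:
                return self.samples[i]
        raise KeyError(f"lead {name!r} not present in {self.lead_names}")

    def has_lead(self, name: str) -> bool:
        want = name.strip().lower()
        return any(label.lower() == want for label in self.lead_names)

    def with_samples(self, samples: np.ndarray) -> "EcgRecording":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class AnnotationRecord:
    lead: str
    beat: int
    kind: str
    sample: int
    provenance: str = "detected"

    def __post_init__(self) -> None:
        if self.kind not in FIDUCIAL_KINDS:
            raise ValueError(
                f"unknown fiducial kind {self.kind!r}; "
                f"expected one of {FIDUCIAL_KINDS}"
            )
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.lead, self.beat, self.kind)


@dataclass
class AnnotationSet:
    """A collection of per-beat, per-lead fiducial records.

    Manual corrections are represented as ``provenance='override'``
    records; :meth:`resolve` replaces any detected record sharing the
    same (lead, beat, kind) key.  Resolution is idempotent and
    order-independent.
    """

    records: list[AnnotationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def add(self, lead, beat, kind, sample, provenance="detected") -> None:
        self.records.append(
            AnnotationRecord(str(lead), int(beat), str(kind), int(sample),
                             str(provenance))
        )

    def resolve(self) -> "AnnotationSet":
        """Collapse to at most one record per (lead, beat, kind) key,
        override records winning over detected ones.

        Duplicate records within one provenance class must agree on the
        sample index; conflicting duplicates raise.
        """
        chosen: dict[tuple, AnnotationRecord] = {}
        for rec in self.records:
            prev = chosen.get(rec.key)
            if prev is None:
                chosen[rec.key] = rec
                continue
            rank = {"detected": 0, "override": 1}
            if rank[rec.provenance] > rank[prev.provenance]:
                chosen[rec.key] = rec
            elif rank[rec.provenance] == rank[prev.provenance]:
                if rec.sample != prev.sample:
                    raise ValueError(
                        f"conflicting duplicate {rec.provenance} annotations "
                        f"for {rec.key}: samples {prev.sample} and {rec.sample}"
                    )
        out = AnnotationSet(sorted(chosen.values(),
                                   key=lambda r: (r.lead, r.beat,
                                                  FIDUCIAL_KINDS.index(r.kind))))
        return out

    def lookup(self, lead: str, beat: int, kind: str) -> int | None:
        """Resolved sample index for a key, or None."""
        hit = None
        for rec in self.records:
            if rec.key == (lead, beat, kind):
                if hit is None or rec.provenance == "override":
                    hit = rec
        return None if hit is None else hit.sample

    def by_key(self) -> dict[tuple, int]:
        return {rec.key: rec.sample for rec in self.resolve().records}

    def validate_against(self, rec: EcgRecording) -> None:
        """Check bounds and the within-beat ordering invariant
        P_ONSET < P_PEAK < P_OFFSET (when all present)."""
        resolved = self.resolve()
        for ann in resolved.records:
            if not 0 <= ann.sample < rec.n_samples:
                raise ValueError(
                    f"annotation {ann.key} sample {ann.sample} outside "
                    f"recording of length {rec.n_samples}"
                )
        table = resolved.by_key()
        beats = {(lead, beat) for lead, beat, _ in table}
        for lead, beat in beats:
            trio = [table.get((lead, beat, k))
                    for k in ("P_ONSET", "P_PEAK", "P_OFFSET")]
            if all(v is not None for v in trio):
                if not (trio[0] < trio[1] < trio[2]):
                    raise ValueError(
                        f"fiducial ordering violated for lead {lead} "
                        f"beat {beat}: onset={trio[0]}, peak={trio[1]}, "
                        f"offset={trio[2]}"
                    )


# ---------------------------------------------------------------------------
# txt_matrix recording files


def _parse_meta_lines(lines: list[str]) -> dict[str, str]:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip().lower()] = value.strip()
    return meta


def read_recording(path: str | os.PathLike, format: str = "txt_matrix") -> EcgRecording:
    """Read an ECG recording.

    ``txt_matrix``: ``#key=value`` header lines (``fs`` required; optional
    ``units`` in {mV, uV, adc}, ``adc_bits``, ``adc_range_mv``,
    ``source_id``), a header line of lead names, then tab- or
    comma-delimited sample rows.  A same-stem ``.meta`` sidecar with
    ``key=value`` lines is also honoured; embedded headers win.
    """
    if format != "txt_matrix":
        raise ValueError(f"unsupported recording format {format!r}")
    path = os.fspath(path)

    meta: dict[str, str] = {}
    stem, _ = os.path.splitext(path)
    sidecar = stem + ".meta"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta.update(_parse_meta_lines(fh.readlines()))

    with open(path) as fh:
        lines = fh.read().splitlines()
    header_lines = [ln for ln in lines if ln.startswith("#")]
    body = [(i + 1, ln) for i, ln in enumerate(lines)
            if ln.strip() and not ln.startswith("#")]
    meta.update(_parse_meta_lines(header_lines))

    if "fs" not in meta:
        raise ValueError(f"{path}: sampling rate 'fs' missing from metadata")
    fs = float(meta["fs"])

    if not body:
        raise ValueError(f"{path}: no lead-name header line found")
    _, head = body[0]
    delim = "\t" if "\t" in head else ","
    lead_names = tuple(canonical_lead(tok) for tok in head.split(delim)
                       if tok.strip())

    rows = []
    for lineno, line in body[1:]:
        toks = [t for t in line.split(delim)]
        if len(toks) != len(lead_names):
            raise ValueError(
                f"{path}: ragged row at line {lineno}: "
                f"{len(toks)} columns, expected {len(lead_names)}"
            )
        rows.append([float(t) for t in toks])
    samples = (np.array(rows, dtype=float).T if rows
               else np.empty((len(lead_names), 0)))

    adc_bits = int(meta["adc_bits"]) if "adc_bits" in meta else None
    adc_range = float(meta["adc_range_mv"]) if "adc_range_mv" in meta else None

    units = meta.get("units", "mV").lower()
    if units == "mv":
        pass
    elif units in ("uv", "µv"):
        samples = samples / 1000.0
    elif units == "adc":
        if adc_bits is None or adc_range is None:
            raise ValueError(
                f"{path}: units=adc requires adc_bits and adc_range_mv metadata"
            )
        samples = samples * (adc_range / 2 ** adc_bits)
    else:
        raise ValueError(f"{path}: unknown units {units!r}")

    return EcgRecording(
        samples=samples, fs=fs, lead_names=lead_names,
        adc_bits=adc_bits, adc_range_mv=adc_range,
        source_id=meta.get("source_id", ""),
    )


def write_recording(rec: EcgRecording, path: str | os.PathLike,
                    format: str = "txt_matrix", delimiter: str = "\t") -> None:
    """Write a recording in the txt_matrix dialect (amplitudes in mV,
    6 decimal places — finer than one 16-bit quantum over 10 mV)."""
    if format != "txt_matrix":
        raise ValueError(f"unsupported recording format {format!r}")
    if not rec.fs > 0:
        raise ValueError("refusing to write recording with non-positive fs")
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write(f"#fs={rec.fs:g}\n")
        fh.write("#units=mV\n")
        if rec.adc_bits is not None:
            fh.write(f"#adc_bits={rec.adc_bits}\n")
        if rec.adc_range_mv is not None:
            fh.write(f"#adc_range_mv={rec.adc_range_mv:g}\n")
        if rec.source_id:
            fh.write(f"#source_id={rec.source_id}\n")
        fh.write(delimiter.join(rec.lead_names) + "\n")
        for row in rec.samples.T:
            fh.write(delimiter.join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# annotation CSV


def read_annotations(path: str | os.PathLike) -> AnnotationSet:
    """Read an annotation CSV (columns lead,beat,kind,sample,provenance).
    An empty file yields an empty set; unknown kinds are a hard error."""
    path = os.fspath(path)
    if os.path.getsize(path) == 0:
        return AnnotationSet()
    df = pd.read_csv(path, dtype={"lead": str, "kind": str, "provenance": str})
    if df.empty:
        return AnnotationSet()
    out = AnnotationSet()
    for row in df.itertuples(index=False):
        out.add(row.lead, int(row.beat), row.kind, int(row.sample),
                getattr(row, "provenance", "detected"))
    return out


def write_annotations(ann: AnnotationSet, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(r.lead, r.beat, r.kind, r.sample, r.provenance)
         for r in ann.records],
        columns=["lead", "beat", "kind", "sample", "provenance"],
    )
    df.to_csv(os.fspath(path), index=False)


# ---------------------------------------------------------------------------
# feature / cohort tables (thin pandas wrappers with a stable float format)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(os.fspath(path), index=False, float_format="%.10g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(os.fspath(path))
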