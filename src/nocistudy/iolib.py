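"""Readers and writers for the pipeline's external formats.

Everything downstream of this module is pure computation on in-memory
types.  On-disk formats are deliberately plain text so fixtures are
diff-able and generator-writable:

* sweep tables -- delimited numeric table with a ``#``-prefixed sidecar
  header carrying sample rate, clamp mode and units;
* GMT gene-set collections (MSigDB dialect);
* TSV differential-expression tables (gene, log2fc, pvalue, qvalue);
* TSV candidate-variant tables with per-individual genotype columns.

Unit conventions, fixed package-wide: time in ms, membrane voltage in mV,
injected current in pA (current clamp), recorded current in nA (voltage
clamp), resistance in GOhm, temperature in degC.  GOhm x pA = mV, which
keeps the Ohm's-law code unit-free.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ValidationError",
    "SweepRecording",
    "RunConfig",
    "GeneSet",
    "DegRecord",
    "VariantRecord",
    "read_sweeps",
    "write_sweeps",
    "read_gmt",
    "write_gmt",
    "read_deg_table",
    "write_deg_table",
    "read_variant_table",
    "write_variant_table",
]

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True)
class SweepRecording:
    """One stimulus/response time series from a patch-clamp protocol.

    Parameters
    ----------
    sample_rate
        Samples per second.  Must agree with the time grid to 1 ppm.
    clamp_mode
        ``"current_clamp"`` (response in mV, stimulus in pA) or
        ``"voltage_clamp"`` (response in nA, stimulus in mV or degC for
        temperature ramps).
    time, response, stimulus
        Equal-length arrays; ``time`` is a strictly increasing uniform
        grid in ms.
    metadata
        Free-form key -> text mapping (spike times, ground-truth
        parameters of synthetic sweeps, ...).
    """

    sample_rate: float
    clamp_mode: str
    time: np.ndarray
    response: np.ndarray
    stimulus: np.ndarray
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.response, dtype=float)
        s = np.asarray(self.stimulus, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", r)
        object.__setattr__(self, "stimulus", s)
        if self.clamp_mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise ValidationError(f"unknown clamp_mode {self.clamp_mode!r}")
        if not (len(t) == len(r) == len(s)) or len(t) < 2:
            raise ValidationError(
                "time, response and stimulus must share a length >= 2"
            )
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError("time grid is not strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
            raise ValidationError("time grid is not uniform")
        # sample_rate [1/s] * dt [ms] must equal 1000 within 1 ppm
        if abs(self.sample_rate * dt[0] - 1000.0) > 1e-3:
            raise ValidationError(
                f"sample_rate {self.sample_rate} inconsistent with time step "
                f"{dt[0]} ms"
            )

    @property
    def dt(self) -> float:
        """Sample interval in ms."""
        return 1000.0 / self.sample_rate

    @property
    def n_samples(self) -> int:
        return len(self.time)


@dataclass
class RunConfig:
    """Named numeric settings shared across the pipeline.

    Defaults mirror the recording protocols this package models: input
    resistance from four -5 pA hyperpolarizing steps at 5 kHz, rheobase
    from 5 pA incrementing 50-ms block pulses with action potentials
    recorded at 20 kHz, 5-s ramps at 1x/2x/3x rheobase and a 20-s block
    at 2x rheobase sampled at 5 kHz, heat ramps from room temperature to
    50 degC in 5 s with a -0.2 nA responsiveness criterion.
    """

    seed: int = 0
    # sample rates (Hz)
    fs_ir: float = 5000.0
    fs_ap: float = 20000.0
    fs_ramp: float = 5000.0
    fs_block: float = 5000.0
    fs_heat: float = 1000.0
    # protocol geometry
    ir_step_pa: float = -5.0
    ir_n_steps: int = 4
    ir_step_dur_ms: float = 200.0
    rheo_step_dur_ms: float = 50.0
    rheo_increment_pa: float = 5.0
    rheo_i_max_pa: float = 500.0
    ramp_dur_ms: float = 5000.0
    block_dur_ms: float = 20000.0
    block_bin_ms: float = 2500.0
    heat_t_start_c: float = 22.0
    heat_t_end_c: float = 50.0
    heat_ramp_dur_ms: float = 5000.0
    heat_threshold_na: float = -0.2
    # detection / extraction
    ap_detect_level_mv: float = 0.0
    ap_refractory_ms: float = 2.0
    smooth_window_ms: float = 0.35
    prominence_mv_per_ms: float = 5.0
    dvdt_threshold_fallback: float = 10.0
    baseline_fraction: float = 0.2
    # statistics / enrichment
    alpha: float = 0.05
    gsea_permutations: int = 1000
    gsea_weight: float = 1.0
    similarity_cutoff: float = 0.375
    combine_k: float = 0.5
    gsea_p_cut: float = 0.05
    gsea_fdr_cut: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "fs_ir", "fs_ap", "fs_ramp", "fs_block", "fs_heat",
            "ir_step_dur_ms", "rheo_step_dur_ms", "rheo_increment_pa",
            "ramp_dur_ms", "block_dur_ms", "block_bin_ms",
            "heat_ramp_dur_ms", "ap_refractory_ms", "smooth_window_ms",
            "prominence_mv_per_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (unique, order-preserving)."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"gene set {self.name!r} has duplicates")

    def __len__(self) -> int:
        return len(self.members)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass(frozen=True)
class DegRecord:
    """One differential-expression result row."""

    gene: str
    log2fc: float
    pvalue: float
    qvalue: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.qvalue <= 1.0:
            raise ValidationError(
                f"gene {self.gene!r}: qvalue {self.qvalue} outside [0, 1]"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One candidate variant with per-individual genotypes.

    ``genotypes`` maps individual id to a genotype string: two alleles
    separated by ``/`` for autosomes, a single allele for the male X.
    ``inheritance`` is the proposed mode: AR, XLR, XLD or NA.
    """

    gene: str
    genomic_change: str
    zygosity_claimed: str
    inheritance: str
    genotypes: Mapping[str, str]
    panel: str = ""
    cadd: float | None = None
    population_freq: float | None = None


# ---------------------------------------------------------------------------
# sweep tables
# ---------------------------------------------------------------------------

_HEADER_PREFIX = "#"


def write_sweeps(path: str | Path, sweeps: Sequence[SweepRecording]) -> None:
    """Write sweeps sharing one time grid to a delimited text table.

    Layout: ``#``-prefixed ``key: value`` header lines (sample rate,
    clamp mode, per-sweep JSON metadata) followed by a CSV body with
    columns ``time, stim0, resp0, stim1, resp1, ...``.  Values are
    printed with 9 decimal digits so a read-back round-trip is faithful
    to 1e-9.
    """
    if not sweeps:
        raise ValidationError("no sweeps to write")
    first = sweeps[0]
    for sw in sweeps[1:]:
        if sw.sample_rate != first.sample_rate or sw.clamp_mode != first.clamp_mode:
            raise ValidationError("sweeps in one file must share rate and mode")
        if sw.n_samples != first.n_samples:
            raise ValidationError("sweeps in one file must share the time grid")
    path = Path(path)
    cols = ["time"]
    data = [first.time]
    for i, sw in enumerate(sweeps):
        cols += [f"stim{i}", f"resp{i}"]
        data += [sw.stimulus, sw.response]
    body = pd.DataFrame(dict(zip(cols, data)))
    meta = [dict(sw.metadata) for sw in sweeps]
    with path.open("w") as fh:
        fh.write(f"{_HEADER_PREFIX} sample_rate_hz: {first.sample_rate!r}\n")
        fh.write(f"{_HEADER_PREFIX} clamp_mode: {first.clamp_mode}\n")
        fh.write(f"{_HEADER_PREFIX} n_sweeps: {len(sweeps)}\n")
        fh.write(f"{_HEADER_PREFIX} metadata: {json.dumps(meta)}\n")
        body.to_csv(fh, index=False, float_format="%.9f")


def read_sweeps(
    path: str | Path,
    clamp_mode: str | None = None,
    sample_rate: float | None = None,
) -> list[SweepRecording]:
    """Read a sweep table written by :func:`write_sweeps`.

    ``clamp_mode`` / ``sample_rate`` override the header when the file
    comes from an external source without one.  Non-uniform or
    non-monotone time grids are rejected.
    """
    path = Path(path)
    header: dict[str, str] = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith(_HEADER_PREFIX):
                break
            n_header += 1
            key, _, value = line[len(_HEADER_PREFIX):].strip().partition(":")
            header[key.strip()] = value.strip()
    body = pd.read_csv(path, skiprows=n_header)
    if "time" not in body.columns:
        raise FormatError(f"{path}: missing required 'time' column")
    mode = clamp_mode or header.get("clamp_mode")
    if mode is None:
        raise FormatError(f"{path}: clamp_mode absent from header and call")
    if sample_rate is not None:
        fs = float(sample_rate)
    elif "sample_rate_hz" in header:
        fs = float(header["sample_rate_hz"])
    else:
        t = body["time"].to_numpy(float)
        if len(t) < 2 or t[1] == t[0]:
            raise FormatError(f"{path}: cannot infer sample rate")
        fs = 1000.0 / (t[1] - t[0])
    meta: list[dict[str, str]] = []
    if "metadata" in header:
        try:
            meta = json.loads(header["metadata"])
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: malformed metadata header") from exc
    pairs = []
    i = 0
    while f"stim{i}" in body.columns or f"resp{i}" in body.columns:
        if not (f"stim{i}" in body.columns and f"resp{i}" in body.columns):
            raise FormatError(f"{path}: unpaired stim/resp columns for sweep {i}")
        pairs.append((f"stim{i}", f"resp{i}"))
        i += 1
    if not pairs:
        raise FormatError(f"{path}: no (stimulus, response) column pairs")
    t = body["time"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValidationError(f"{path}: time not strictly increasing")
    out = []
    for i, (cs, cr) in enumerate(pairs):
        out.append(
            SweepRecording(
                sample_rate=fs,
                clamp_mode=mode,
                time=t,
                stimulus=body[cs].to_numpy(float),
                response=body[cr].to_numpy(float),
                metadata=meta[i] if i < len(meta) else {},
            )
        )
    return out


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: ``name <tab> description <tab> member...``.

    Duplicate members within a set are dropped (first occurrence kept);
    a line with fewer than three fields is a format error.
    """
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
        name, desc, *members = fields
        members = [m for m in members if m]
        unique = tuple(dict.fromkeys(members))
        if not unique:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
        sets.append(GeneSet(name=name, description=desc, members=unique))
    return sets


def write_gmt(path: str | Path, sets: Iterable[GeneSet]) -> None:
    lines = [
        "\t".join([gs.name, gs.description, *gs.members]) for gs in sets
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------

_DEG_COLUMNS = ["gene", "log2fc", "pvalue", "qvalue"]


def read_deg_table(path: str | Path) -> list[DegRecord]:
    """Read a TSV of DE results with columns gene, log2fc, pvalue, qvalue."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate gene {dup!r}")
    return [
        DegRecord(str(g), float(f), float(p), float(q))
        for g, f, p, q in zip(df.gene, df.log2fc, df.pvalue, df.qvalue)
    ]


def write_deg_table(path: str | Path, records: Sequence[DegRecord]) -> None:
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "log2fc": [r.log2fc for r in records],
            "pvalue": [r.pvalue for r in records],
            "qvalue": [r.qvalue for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# candidate-variant tables
# ---------------------------------------------------------------------------

_VARIANT_FIXED = [
    "gene", "genomic_change", "zygosity", "inheritance", "panel",
    "cadd", "population_freq",
]


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a TSV variant table.

    Fixed columns: gene, genomic_change, zygosity, inheritance, panel,
    cadd, population_freq (the latter two may be empty / NA).  Every
    additional column named ``genotype_<id>`` carries the genotype of
    individual ``<id>``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("gene", "genomic_change", "inheritance") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    geno_cols = [c for c in df.columns if c.startswith("genotype_")]
    if not geno_cols:
        raise FormatError(f"{path}: no genotype_<individual> columns")
    out = []
    for _, row in df.iterrows():
        cadd = row.get("cadd", "")
        freq = row.get("population_freq", "")
        out.append(
            VariantRecord(
                gene=row["gene"],
                genomic_change=row["genomic_change"],
                zygosity_claimed=row.get("zygosity", "") or "homozygous",
                inheritance=row["inheritance"] or "NA",
                genotypes={
                    c[len("genotype_"):]: row[c] for c in geno_cols if row[c]
                },
                panel=row.get("panel", ""),
                cadd=float(cadd) if cadd not in ("", "NA") else None,
                population_freq=float(freq) if freq not in ("", "NA") else None,
            )
        )
    return out


def write_variant_table(path: str | Path, records: Sequence[VariantRecord]) -> None:
    individuals: list[str] = []
    for r in records:
        for ind in r.genotypes:
            if ind not in individuals:
                individuals.append(ind)
    rows = []
    for r in records:
        row = {
            "gene": r.gene,
            "genomic_change": r.genomic_change,
            "zygosity": r.zygosity_claimed,
            "inheritance": r.inheritance,
            "panel": r.panel,
            "cadd": "" if r.cadd is None else repr(r.cadd),
            "population_freq": "" if r.population_freq is None else repr(r.population_freq),
        }
        for ind in individuals:
            row[f"genotype_{ind}"] = r.genotypes.get(ind, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
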