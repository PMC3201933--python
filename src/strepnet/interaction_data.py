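"""Experimental-side domain types, interaction classification, and on-disk formats.

The experiment measures directional, compound-mediated interactions between
*Streptomyces* isolates: a *sender* conditions agar through a filter, a
*receiver* is pinned onto the conditioned agar, and the receiver's colony
appearance time (days since inoculation) is compared with its appearance time
on non-conditioned control agar.  Delays mean inhibition, speedups mean growth
promotion; inhibition of aerial mycelium formation is scored separately as a
boolean flag and is treated as a negative interaction when enabled.

Conventions shared by every module in this package:

* matrices are receiver x sender: entry ``(i, j)`` is the effect of sender
  ``j`` on receiver ``i``;
* appearance times are floats in days; ``numpy.inf`` encodes a complete
  inhibition (colony never appeared) and ``numpy.nan`` a defective/missing
  well;
* diagonal entries are stored (self-inhibition occurs in real data) but every
  statistic excludes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NEG",
    "NONE",
    "POS",
    "Thresholds",
    "SignedMatrix",
    "InteractionExperiment",
    "classify_interactions",
    "to_continuous",
    "read_experiment",
    "write_experiment",
    "read_signed",
    "write_signed",
]

# sign codes used in SignedMatrix.values
NEG = -1
NONE = 0
POS = 1


class ExperimentFormatError(ValueError):
    """Raised for malformed on-disk data or irreconcilable isolate ids."""


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds (all in days).

    ``neg_delay_days``
        minimal median delay relative to control that counts as inhibition
        (default 1 d; 3 d selects only strong inhibitions).
    ``pos_speedup_days``
        minimal median speedup that counts as growth promotion (default 0.5 d,
        i.e. 12 h earlier colony appearance).
    ``include_aerial``
        whether aerial-mycelium inhibitions count as negative interactions.
    ``complete_code_days``
        the appearance time assigned to complete (and aerial) inhibitions in
        continuous analyses (default 10 d).
    """

    neg_delay_days: float = 1.0
    strong_delay_days: float = 3.0
    pos_speedup_days: float = 0.5
    include_aerial: bool = True
    complete_code_days: float = 10.0

    def __post_init__(self) -> None:
        for name in ("neg_delay_days", "strong_delay_days", "pos_speedup_days",
                     "complete_code_days"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.strong_delay_days < self.neg_delay_days:
            raise ValueError("strong_delay_days must be >= neg_delay_days")


@dataclass
class SignedMatrix:
    """Classified interaction matrix.

    ``values[i, j]`` is the sign of the effect of sender ``j`` on receiver
    ``i`` (NEG/NONE/POS); ``missing[i, j]`` marks entries whose underlying
    wells were defective or whose replicates were inconsistent.  The diagonal
    is stored but excluded from all statistics.
    """

    values: np.ndarray
    missing: np.ndarray
    isolates: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        k = len(self.isolates)
        if self.values.shape != (k, k) or self.missing.shape != (k, k):
            raise ValueError("SignedMatrix must be square over the isolate list")
        if not np.isin(self.values, (NEG, NONE, POS)).all():
            raise ValueError("values must be in {-1, 0, 1}")

    @property
    def k(self) -> int:
        return len(self.isolates)

    def off_diagonal(self) -> np.ndarray:
        """Boolean mask of usable entries: off-diagonal and not missing."""
        return ~self.missing & ~np.eye(self.k, dtype=bool)

    def binarize(self, *, negative: bool = True, positive: bool = False) -> "SignedMatrix":
        """Collapse to a 0/1 matrix keeping the selected sign(s) as 1."""
        keep = np.zeros_like(self.values)
        if negative:
            keep |= self.values == NEG
        if positive:
            keep |= self.values == POS
        return SignedMatrix(keep.astype(np.int8), self.missing.copy(), list(self.isolates))

    def transpose(self) -> "SignedMatrix":
        return SignedMatrix(self.values.T.copy(), self.missing.T.copy(), list(self.isolates))


@dataclass
class InteractionExperiment:
    """Bundle of everything the interaction experiment measured.

    appearance_time : (K, K, R) float array
        days until the receiver colony appears on sender-conditioned agar;
        inf = complete inhibition, nan = defective well.
    control_time : (K, Rc) float array
        appearance times on non-conditioned agar (controls may have a
        different replicate count).
    aerial_inhibited : (K, K) float array
        1.0 aerial mycelium inhibited, 0.0 not, nan unknown.
    grain_of : list of grain labels, one per isolate (soil-grain of origin).
    seq16s : aligned 16S rRNA sequences (A/C/G/T/-), equal length.
    qual_mask : per-position high-quality flags, same length as the alignment.
    """

    isolates: list[str]
    appearance_time: np.ndarray
    control_time: np.ndarray
    aerial_inhibited: np.ndarray
    grain_of: list[str]
    seq16s: list[str] = field(default_factory=list)
    qual_mask: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.appearance_time = np.asarray(self.appearance_time, dtype=float)
        self.control_time = np.asarray(self.control_time, dtype=float)
        self.aerial_inhibited = np.asarray(self.aerial_inhibited, dtype=float)
        self.validate()

    @property
    def k(self) -> int:
        return len(self.isolates)

    @property
    def n_replicates(self) -> int:
        return self.appearance_time.shape[2]

    def validate(self) -> None:
        k = self.k
        if self.appearance_time.ndim != 3 or self.appearance_time.shape[:2] != (k, k):
            raise ValueError("appearance_time must be (K, K, R)")
        if self.aerial_inhibited.shape != (k, k):
            raise ValueError("aerial_inhibited must share the (K, K) shape")
        if self.control_time.ndim != 2 or self.control_time.shape[0] != k:
            raise ValueError("control_time must be (K, Rc)")
        if len(self.grain_of) != k:
            raise ValueError("every isolate needs a grain label")
        if self.seq16s:
            if len(self.seq16s) != k or len(self.qual_mask) != k:
                raise ValueError("seq16s/qual_mask must cover all isolates")
            lengths = {len(s) for s in self.seq16s}
            if len(lengths) > 1:
                raise ValueError("aligned 16S sequences must have equal length")
            if any(len(m) != len(s) for s, m in zip(self.seq16s, self.qual_mask)):
                raise ValueError("quality masks must match sequence length")

    def median_control(self) -> np.ndarray:
        """Per-receiver median control appearance time.

        Raises if any receiver lacks a valid (finite) control replicate, and
        names the offending receivers.
        """
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(np.where(np.isfinite(self.control_time),
                                        self.control_time, np.nan), axis=1)
        bad = np.flatnonzero(~np.isfinite(med))
        if bad.size:
            names = [self.isolates[i] for i in bad]
            raise ExperimentFormatError(
                f"receivers with no valid control replicate: {names}")
        return med


def _median_times(exp: InteractionExperiment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Median appearance time per entry over valid (non-nan) replicates.

    Returns (median, n_valid, inconsistent-free delays array) building blocks
    shared by classification and the continuous transform.
    """
    t = exp.appearance_time
    valid = ~np.isnan(t)
    n_valid = valid.sum(axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(t, axis=2)
    return med, n_valid, t


def classify_interactions(exp: InteractionExperiment, th: Thresholds | None = None) -> SignedMatrix:
    """Classify each (receiver, sender) entry as NEG / POS / NONE / missing.

    Per entry the median appearance time over valid replicates is compared to
    the receiver's median control time.  Negative interactions are median
    delays > ``neg_delay_days``, complete inhibitions (no colony ever
    appeared), or aerial-mycelium inhibitions when ``include_aerial`` is on.
    Positive interactions are median speedups >= ``pos_speedup_days``.  An
    entry is missing when every replicate was defective, or when replicates
    disagree in sign with both magnitudes beyond ``neg_delay_days``
    (inconsistent replicas).
    """
    th = th or Thresholds()
    ctrl = exp.median_control()
    med, n_valid, t = _median_times(exp)
    delays = t - ctrl[:, None, None]  # (K, K, R); inf stays inf

    with np.errstate(invalid="ignore"):
        inconsistent = (
            np.nansum(delays > th.neg_delay_days, axis=2).astype(bool)
            & np.nansum(delays < -th.neg_delay_days, axis=2).astype(bool)
        )
    missing = (n_valid == 0) | inconsistent

    med_delay = med - ctrl[:, None]
    aerial = exp.aerial_inhibited == 1.0
    with np.errstate(invalid="ignore"):
        neg = (med_delay > th.neg_delay_days) | np.isinf(med)
        if th.include_aerial:
            neg |= aerial
        pos = -med_delay >= th.pos_speedup_days

    values = np.zeros((exp.k, exp.k), dtype=np.int8)
    values[pos] = POS
    values[neg] = NEG  # NEG takes precedence over POS
    values[missing] = NONE
    return SignedMatrix(values, missing, list(exp.isolates))


def to_continuous(exp: InteractionExperiment, th: Thresholds | None = None) -> np.ndarray:
    """Continuous receiver x sender matrix of median appearance times (days).

    Complete inhibitions and aerial-mycelium inhibitions are set to
    ``complete_code_days`` (treating aerial inhibition as complete); entries
    with no valid replicate are nan.
    """
    th = th or Thresholds()
    med, n_valid, _ = _median_times(exp)
    out = med.copy()
    with np.errstate(invalid="ignore"):
        complete = np.isinf(med) | (exp.aerial_inhibited == 1.0)
    out[complete] = th.complete_code_days
    out[n_valid == 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# on-disk formats
#
# appearance_rep<r>.tsv : K x K matrix TSV, first row/column isolate ids,
#                         tokens = decimal days | INF | NA
# aerial.tsv            : K x K matrix TSV of {0, 1, NA}
# control_rep<r>.tsv    : two columns (isolate, days)
# grains.tsv            : two columns (isolate, grain)
# seq16s.fasta          : aligned sequences, gaps "-"
# qual_mask.fasta       : records of "0"/"1" strings, equal length
# ---------------------------------------------------------------------------

def _parse_cell(token: str, path: Path, line: int) -> float:
    token = token.strip()
    if token == "NA":
        return np.nan
    if token == "INF":
        return np.inf
    try:
        return float(token)
    except ValueError as exc:
        raise ExperimentFormatError(f"{path}:{line}: bad cell {token!r}") from exc


def _read_matrix_tsv(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    lines = Path(path).read_text().rstrip("\n").split("\n")
    header = lines[0].split("\t")
    senders = [h.strip() for h in header[1:]]
    receivers: list[str] = []
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(senders) + 1:
            raise ExperimentFormatError(f"{path}:{ln}: expected {len(senders) + 1} columns")
        receivers.append(cells[0].strip())
        rows.append([_parse_cell(c, path, ln) for c in cells[1:]])
    return receivers, senders, np.asarray(rows, dtype=float)


def _format_cell(x: float) -> str:
    if np.isnan(x):
        return "NA"
    if np.isinf(x):
        return "INF"
    if x == int(x):
        return f"{x:.1f}"
    return repr(float(x))


def _write_matrix_tsv(path: Path, isolates: Sequence[str], m: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["receiver\\sender", *isolates]) + "\n")
        for name, row in zip(isolates, m):
            fh.write("\t".join([name, *(_format_cell(x) for x in row)]) + "\n")


def _read_two_column(path: Path, value_parser) -> dict[str, object]:
    out: dict[str, object] = {}
    for ln, line in enumerate(Path(path).read_text().rstrip("\n").split("\n"), start=1):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ExperimentFormatError(f"{path}:{ln}: expected 2 columns")
        out[parts[0].strip()] = value_parser(parts[1].strip())
    return out


def read_experiment(directory: str | Path) -> InteractionExperiment:
    """Read an experiment bundle from a directory of the canonical files."""
    d = Path(directory)
    rep_paths = sorted(d.glob("appearance_rep*.tsv"))
    if not rep_paths:
        raise ExperimentFormatError(f"no appearance_rep*.tsv files under {d}")
    receivers, senders, first = _read_matrix_tsv(rep_paths[0])
    if receivers != senders:
        raise ExperimentFormatError(f"{rep_paths[0]}: receiver and sender ids differ")
    isolates = receivers
    reps = [first]
    for p in rep_paths[1:]:
        r, s, m = _read_matrix_tsv(p)
        if r != isolates or s != isolates:
            raise ExperimentFormatError(f"{p}: isolate ids disagree with {rep_paths[0]}")
        reps.append(m)
    appearance = np.stack(reps, axis=2)

    r, s, aerial = _read_matrix_tsv(d / "aerial.tsv")
    if r != isolates or s != isolates:
        raise ExperimentFormatError("aerial.tsv: isolate ids disagree")

    ctrl_paths = sorted(d.glob("control_rep*.tsv"))
    if not ctrl_paths:
        raise ExperimentFormatError(f"no control_rep*.tsv files under {d}")
    ctrl_cols = []
    for p in ctrl_paths:
        table = _read_two_column(p, lambda v: _parse_cell(v, p, 0))
        if set(table) != set(isolates):
            raise ExperimentFormatError(f"{p}: isolate ids disagree with appearance files")
        ctrl_cols.append([table[i] for i in isolates])
    control = np.asarray(ctrl_cols, dtype=float).T

    grains = _read_two_column(d / "grains.tsv", str)
    if set(grains) != set(isolates):
        raise ExperimentFormatError("grains.tsv: isolate ids disagree")
    grain_of = [str(grains[i]) for i in isolates]

    seqs: list[str] = []
    quals: list[np.ndarray] = []
    fasta = d / "seq16s.fasta"
    if fasta.exists():
        seq_by_id = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        qual_by_id = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(d / "qual_mask.fasta"), "fasta")}
        if set(seq_by_id) != set(isolates) or set(qual_by_id) != set(isolates):
            raise ExperimentFormatError("16S/quality records do not match isolate ids")
        for i in isolates:
            seqs.append(seq_by_id[i])
            quals.append(np.frombuffer(qual_by_id[i].encode(), dtype=np.uint8) == ord("1"))

    return InteractionExperiment(
        isolates=isolates,
        appearance_time=appearance,
        control_time=control,
        aerial_inhibited=aerial,
        grain_of=grain_of,
        seq16s=seqs,
        qual_mask=quals,
    )


def write_experiment(exp: InteractionExperiment, directory: str | Path) -> None:
    """Write an experiment bundle; inverse of :func:`read_experiment`."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for r in range(exp.n_replicates):
        _write_matrix_tsv(d / f"appearance_rep{r + 1}.tsv", exp.isolates,
                          exp.appearance_time[:, :, r])
    _write_matrix_tsv(d / "aerial.tsv", exp.isolates, exp.aerial_inhibited)
    for r in range(exp.control_time.shape[1]):
        with open(d / f"control_rep{r + 1}.tsv", "w") as fh:
            for name, v in zip(exp.isolates, exp.control_time[:, r]):
                fh.write(f"{name}\t{_format_cell(v)}\n")
    with open(d / "grains.tsv", "w") as fh:
        for name, g in zip(exp.isolates, exp.grain_of):
            fh.write(f"{name}\t{g}\n")
    if exp.seq16s:
        SeqIO.write(
            (SeqRecord(Seq(s), id=i, description="") for i, s in zip(exp.isolates, exp.seq16s)),
            str(d / "seq16s.fasta"), "fasta")
        SeqIO.write(
            (SeqRecord(Seq("".join("1" if b else "0" for b in m)), id=i, description="")
             for i, m in zip(exp.isolates, exp.qual_mask)),
            str(d / "qual_mask.fasta"), "fasta")


_SIGN_TOKEN = {NEG: "-1", NONE: "0", POS: "1"}


def write_signed(matrix: SignedMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["receiver\\sender", *matrix.isolates]) + "\n")
        for i, name in enumerate(matrix.isolates):
            cells = ["NA" if matrix.missing[i, j] else _SIGN_TOKEN[int(matrix.values[i, j])]
                     for j in range(matrix.k)]
            fh.write("\t".join([name, *cells]) + "\n")


def read_signed(path: str | Path) -> SignedMatrix:
    receivers, senders, m = _read_matrix_tsv(Path(path))
    if receivers != senders:
        raise ExperimentFormatError(f"{path}: receiver and sender ids differ")
    missing = np.isnan(m)
    values = np.where(missing, 0, m).astype(np.int8)
    return SignedMatrix(values, missing, receivers)
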