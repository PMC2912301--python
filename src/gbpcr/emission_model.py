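"""Genotype-emission model: P(detected call | normal genotype, aberration class).

The observable at each SNP is the collapsed genotype call
``y ∈ {NoCall, Het, NHet}``.  Conditional on the true normal-cell genotype
``x ∈ {Het, Hom}`` and the aberration class ``w`` of the surrounding region,
the call is drawn from a categorical emission distribution.  The abnormal-cell
genotype (empty / Het / Hom) is fully determined by ``(x, w)`` and is
therefore composed analytically into the table rather than represented at run
time.  The IBD/UPD class ``w = -3`` has a single unconditional row: inside a
copy-neutral LOH region the detected genotype no longer depends on the
normal-cell genotype.

The module also implements the sample-noise adjustment of the NoCall-related
entries: the NoCall probability in a target sample is the reference
probability scaled by the ratio of observed-to-reference NoCall rates per
class, reflecting a multiplicative sample-noise factor on top of the
technical NoCall component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

# Observed-call codes (order is the column order of every emission row).
NOCALL, HET, NHET = 0, 1, 2
Y_LABELS = ("NoCall", "Het", "NHet")

# Normal-cell genotype codes.
X_HET, X_HOM = 0, 1
X_LABELS = ("Het", "Hom")

#: Copy-number event classes carrying their own conditional rows.  The gain
#: class (w = 1) shares the w = 0 rows: genotype detection does not change
#: between normal and gained regions.
Z_CODES = (-2, -1, 0, 2)
#: IBD/UPD class code (single unconditional row).
UPD_CODE = -3

_ROW_TOL = 1e-12


def _check_row(row: np.ndarray, name: str) -> None:
    if np.any(row < 0) or np.any(row > 1):
        raise ValidationError(f"emission row {name} has entries outside [0, 1]: {row}")
    if abs(row.sum() - 1.0) > _ROW_TOL:
        raise ValidationError(f"emission row {name} does not sum to 1: sum={row.sum()!r}")


@dataclass(frozen=True)
class EmissionParamTable:
    """Emission probabilities P(y | x, w) plus the unconditional IBD/UPD row.

    Parameters
    ----------
    cond
        Array of shape ``(2, 4, 3)`` indexed by ``(x, z_index, y)`` with the
        z axis following :data:`Z_CODES`.
    upd_row
        Length-3 probability vector P(y | w = -3).
    adjusted
        Provenance tag: ``False`` for reference defaults, ``True`` once the
        NoCall entries have been rescaled to a sample's noise level.
    """

    cond: np.ndarray
    upd_row: np.ndarray
    adjusted: bool = False

    def __post_init__(self):
        cond = np.asarray(self.cond, dtype=float)
        upd = np.asarray(self.upd_row, dtype=float)
        if cond.shape != (2, len(Z_CODES), 3):
            raise ValidationError(f"cond must have shape (2, 4, 3), got {cond.shape}")
        if upd.shape != (3,):
            raise ValidationError(f"upd_row must have shape (3,), got {upd.shape}")
        for xi, xlab in enumerate(X_LABELS):
            for zi, z in enumerate(Z_CODES):
                _check_row(cond[xi, zi], f"(x={xlab}, w={z})")
        _check_row(upd, "(w=-3)")
        object.__setattr__(self, "cond", cond)
        object.__setattr__(self, "upd_row", upd)

    # -- accessors ---------------------------------------------------------

    def _z_index(self, w: int) -> int:
        w = 0 if w == 1 else w  # gain shares the normal rows
        try:
            return Z_CODES.index(w)
        except ValueError:
            raise ValidationError(f"unknown copy-number event class w={w}") from None

    def row(self, x: int, w: int) -> np.ndarray:
        """Emission row for normal genotype ``x`` and class ``w`` (w=1 -> w=0 rows)."""
        if w == UPD_CODE:
            return self.upd_row
        if x not in (X_HET, X_HOM):
            raise ValidationError(f"unknown normal genotype code x={x}")
        return self.cond[x, self._z_index(w)]

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def default(cls) -> "EmissionParamTable":
        """The packaged reference table (documented implementation defaults)."""
        with resources.as_file(
            resources.files("gbpcr.data") / "default_emission_params.tsv"
        ) as p:
            return cls.from_tsv(p)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EmissionParamTable":
        """Parse the emission-parameter TSV (columns x, w, p_nocall, p_het, p_nhet)."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"x": str})
        required = ["x", "w", "p_nocall", "p_het", "p_nhet"]
        if list(df.columns) != required:
            raise ValidationError(
                f"emission table {path}: expected columns {required}, got {list(df.columns)}"
            )
        cond = np.full((2, len(Z_CODES), 3), np.nan)
        upd = np.full(3, np.nan)
        for rec in df.itertuples(index=False):
            probs = np.array([rec.p_nocall, rec.p_het, rec.p_nhet], dtype=float)
            w = int(rec.w)
            if rec.x == "ANY":
                if w != UPD_CODE:
                    raise ValidationError(f"x=ANY is only valid for w=-3, got w={w}")
                upd[:] = probs
            elif rec.x in X_LABELS:
                if w not in Z_CODES:
                    raise ValidationError(f"conditional emission row with invalid w={w}")
                cond[X_LABELS.index(rec.x), Z_CODES.index(w)] = probs
            else:
                raise ValidationError(f"unknown genotype label x={rec.x!r}")
        if np.isnan(cond).any() or np.isnan(upd).any():
            raise ValidationError(f"emission table {path} is missing required rows")
        return cls(cond=cond, upd_row=upd)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for xi, xlab in enumerate(X_LABELS):
            for zi, z in enumerate(Z_CODES):
                rows.append((xlab, z, *self.cond[xi, zi]))
        rows.append(("ANY", UPD_CODE, *self.upd_row))
        pd.DataFrame(
            rows, columns=["x", "w", "p_nocall", "p_het", "p_nhet"]
        ).to_csv(path, sep="\t", index=False)


def snp_outcome_prob(
    y: int | np.ndarray,
    w: int,
    nu: float | np.ndarray,
    params: EmissionParamTable,
) -> float | np.ndarray:
    """Probability of observing call ``y`` under class ``w`` at het-prior ``nu``.

    Marginalizes the unknown normal-cell genotype:
    ``nu * P(y | Het, w) + (1 - nu) * P(y | Hom, w)`` for copy-number classes,
    and the nu-independent P(y | w=-3) for IBD/UPD.
    """
    y_arr = np.asarray(y)
    if np.any((y_arr < 0) | (y_arr > 2)):
        raise ValidationError(f"unknown observed-call code in y={y!r}")
    nu_arr = np.asarray(nu, dtype=float)
    if np.any((nu_arr < 0) | (nu_arr > 1)):
        raise ValidationError("het prior nu must lie in [0, 1]")
    if w == UPD_CODE:
        out = params.upd_row[y_arr] * np.ones_like(nu_arr)
    else:
        out = nu_arr * params.row(X_HET, w)[y_arr] + (1.0 - nu_arr) * params.row(X_HOM, w)[y_arr]
    return out if out.ndim else float(out)


def outcome_prob_track(
    y: np.ndarray, nu: np.ndarray, params: EmissionParamTable, classes
) -> np.ndarray:
    """Per-SNP emission probabilities, shape ``(n, len(classes))``."""
    cols = [snp_outcome_prob(y, w, nu, params) for w in classes]
    return np.column_stack(cols)


def reference_nocall_rate(params: EmissionParamTable, z: int) -> float:
    """Expected NoCall rate in regions of class ``z`` under a Het marginal of 1/2.

    With the four allele combinations AA, AB, BA, BB equally likely for a
    generic SNP, P(x = Het) = 1/2, so the class-level rate is the plain
    average of the Het- and Hom-conditional NoCall entries.
    """
    if z == UPD_CODE:
        raise ValidationError(
            "the IBD/UPD row has no reference rate of its own; it is adjusted "
            "with the z=0 factor (see adjust_nocall_params)"
        )
    if z not in Z_CODES:
        raise ValidationError(f"unknown copy-number event class z={z}")
    zi = Z_CODES.index(z)
    return 0.5 * params.cond[X_HET, zi, NOCALL] + 0.5 * params.cond[X_HOM, zi, NOCALL]


def estimate_sample_nocall_rates(
    loh,
    prelim_classes: np.ndarray,
    min_class_size: int = 100,
) -> dict[int, float]:
    """Observed per-class NoCall frequencies r1(z) for the sample to estimate.

    ``prelim_classes`` is a per-SNP class code from a CN-only preliminary
    classification (gain collapsed onto 0).  Classes observed at fewer than
    ``min_class_size`` SNPs fall back to the genome-wide NoCall frequency,
    since rare classes give unstable frequency estimates.
    """
    y = np.asarray(loh.y)
    prelim = np.asarray(prelim_classes)
    if y.size == 0:
        raise ValidationError("cannot estimate NoCall rates from an empty track")
    if prelim.shape != y.shape:
        raise ValidationError(
            f"prelim_classes length {prelim.shape} does not match track length {y.shape}"
        )
    global_rate = float(np.mean(y == NOCALL))
    rates: dict[int, float] = {}
    for z in Z_CODES:
        mask = prelim == z
        n_z = int(mask.sum())
        if n_z < min_class_size:
            logger.warning(
                "class z=%d has %d SNPs (< %d); r1 falls back to the global "
                "NoCall frequency %.4f",
                z, n_z, min_class_size, global_rate,
            )
            rates[z] = global_rate
        else:
            rates[z] = float(np.mean(y[mask] == NOCALL))
    return rates


@dataclass(frozen=True)
class NoCallAdjustment:
    """Per-class NoCall rates of the sample (r1) and the reference table (r2).

    The scaling factor r1(z)/r2(z) estimates the sample-noise multiplier
    theta_s: the NoCall probability decomposes into a technical component
    p_{x,z} (shared across samples) times a sample-noise factor theta_s, so
    the ratio of class-level NoCall rates between two samples isolates the
    ratio of their noise factors.
    """

    r1: dict[int, float] = field(default_factory=dict)
    r2: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, rates in (("r1", self.r1), ("r2", self.r2)):
            for z, r in rates.items():
                if not 0.0 <= r <= 1.0:
                    raise ValidationError(f"{name}({z})={r} outside [0, 1]")

    def factor(self, z: int) -> float:
        r1, r2 = self.r1[z], self.r2[z]
        if r1 == r2:
            return 1.0
        if r2 == 0.0:
            raise ValidationError(
                f"r2({z}) = 0 with r1({z}) = {r1} > 0: scaling factor undefined"
            )
        return r1 / r2

    @classmethod
    def from_sample(
        cls, loh, prelim_classes: np.ndarray, params: EmissionParamTable,
        min_class_size: int = 100,
    ) -> "NoCallAdjustment":
        r1 = estimate_sample_nocall_rates(loh, prelim_classes, min_class_size)
        r2 = {z: reference_nocall_rate(params, z) for z in Z_CODES}
        return cls(r1=r1, r2=r2)


def adjust_nocall_params(
    params: EmissionParamTable, adj: NoCallAdjustment
) -> EmissionParamTable:
    """Rescale the NoCall entries to the sample's noise level.

    For each class z the adjusted probability is
    ``min(1, P_ref(NoCall | x, z) * r1(z)/r2(z))`` (the cap guards very noisy
    samples); the IBD/UPD row uses the z = 0 factor, since the NoCall rate in
    IBD/UPD regions tracks the normal-region rate.  Within each row the Het
    and NHet entries are rescaled proportionally so the row sums to 1,
    preserving their odds while matching the adjusted NoCall mass.
    """
    cond = params.cond.copy()
    for zi, z in enumerate(Z_CODES):
        f = adj.factor(z)
        for xi in (X_HET, X_HOM):
            cond[xi, zi] = _rescale_row(cond[xi, zi], f)
    upd = _rescale_row(params.upd_row.copy(), adj.factor(0))
    return EmissionParamTable(cond=cond, upd_row=upd, adjusted=True)


def _rescale_row(row: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return row.copy()
    p_old = row[NOCALL]
    p_new = min(1.0, p_old * factor)
    out = row.copy()
    out[NOCALL] = p_new
    rest_old = 1.0 - p_old
    rest_new = 1.0 - p_new
    if rest_old > 0.0:
        scale = rest_new / rest_old
        out[HET] *= scale
        out[NHET] *= scale
    else:
        # Degenerate all-NoCall reference row: spread any freed mass evenly.
        out[HET] = out[NHET] = rest_new / 2.0
    # Guard against round-off drifting beyond the row-sum tolerance.
    s = out.sum()
    if abs(s - 1.0) > 1e-13:
        out /= s
    return out
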