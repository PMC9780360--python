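"""Hydrogen-deuterium exchange analysis: uptake, differencing, and EX1 deconvolution.

The EX1 exchange regime produces a bimodal isotopic envelope: a low-mass
subpopulation (the solvent-protected, "closed" conformation) and a
high-mass subpopulation (the exposed, "open" conformation) that slowly
interconvert on the labelling timescale.  The envelope is decomposed by a
least-squares fit of two Gaussian peaks with independent means and areas
but a shared width, and the open-state fraction is the area of the
high-mass component over the total.  The time course of that fraction is
modelled as a first-order closed-to-open interconversion,

    f(t) = f_inf - (f_inf - f0) * exp(-k_open * t).

Centroid uptake follows standard practice: the intensity-weighted mean of
the envelope on the neutral-mass axis, referenced to an undeuterated
control, with no back-exchange correction.  Percent deuteration is
normalised to the theoretical maximum uptake of the peptide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InputError, InsufficientDataError

#: mass added per exchanged amide (D replaces H), Da
DEUTERIUM_INCREMENT_DA = 1.006277
#: proton mass, Da
PROTON_MASS_DA = 1.007276

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


def count_exchangeable(sequence: str) -> int:
    """Number of exchange-competent backbone amides of a peptide.

    The N-terminal residue is excluded (its amide back-exchanges within
    seconds) and prolines are excluded (no amide hydrogen):
    ``(n - 1) - #P at positions 2..n``.
    """
    if not sequence:
        raise InputError("empty peptide sequence")
    for i, aa in enumerate(sequence, start=1):
        if aa not in _AA_ALPHABET:
            raise InputError(f"unknown amino-acid letter {aa!r} at position {i}")
    n = len(sequence)
    n_pro = sequence[1:].count("P")
    return max(0, (n - 1) - n_pro)


@dataclass(frozen=True)
class PeptideRecord:
    """A proteolytic peptide in construct numbering (1-based, inclusive)."""

    peptide_id: str
    sequence: str
    start_res: int
    end_res: int

    def __post_init__(self):
        if self.end_res - self.start_res + 1 != len(self.sequence):
            raise InputError(
                f"peptide {self.peptide_id}: range {self.start_res}-{self.end_res} "
                f"inconsistent with sequence length {len(self.sequence)}"
            )

    @property
    def n_exchangeable(self) -> int:
        return count_exchangeable(self.sequence)

    @property
    def max_uptake_da(self) -> float:
        """Theoretical maximum deuteration level, Da (the 100% reference)."""
        return self.n_exchangeable * DEUTERIUM_INCREMENT_DA


@dataclass
class SpectrumEnvelope:
    """One peptide's m/z-intensity envelope at one timepoint/condition/replicate."""

    peptide_id: str
    condition: str
    timepoint_s: float
    replicate: int
    charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise InputError("mz and intensity must be equal-length 1-D arrays")
        if len(self.mz) < 3:
            raise InputError("envelope needs at least 3 points")
        if np.any(np.diff(self.mz) <= 0):
            raise InputError("mz axis must be strictly increasing")
        if self.charge < 1:
            raise InputError("charge must be >= 1")
        if not np.isfinite(self.intensity).all() or self.intensity.sum() <= 0:
            raise InputError("total intensity must be positive and finite")

    @property
    def neutral_mass(self) -> np.ndarray:
        """Charge-deconvoluted mass axis, Da."""
        return self.charge * (self.mz - PROTON_MASS_DA)


@dataclass(frozen=True)
class UptakeMeasurement:
    peptide_id: str
    condition: str
    timepoint_s: float
    replicate: int
    uptake_da: float
    percent_d: float


@dataclass
class BimodalFit:
    """Shared-width two-Gaussian decomposition of an envelope."""

    mu_low: float
    mu_high: float
    sigma: float
    area_low: float
    area_high: float
    rss: float
    converged: bool

    @property
    def f_open(self) -> float:
        """High-mass (open-state) area over total area."""
        total = self.area_low + self.area_high
        return float(self.area_high / total) if total > 0 else float("nan")


@dataclass
class Ex1Kinetics:
    k_open: float
    f0: float
    f_inf: float
    rss: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.f_inf - (self.f_inf - self.f0) * np.exp(-self.k_open * t)


@dataclass
class HdxConfig:
    """Tunables of the HDX stage."""

    significance_threshold_da: float = 0.4
    deuterium_increment_da: float = DEUTERIUM_INCREMENT_DA
    proton_mass_da: float = PROTON_MASS_DA
    #: id of the exchangeable-amide rule (only one is implemented:
    #: exclude the peptide N-terminus and all prolines)
    exchangeable_rule: str = "nterm1-noproline"

    def __post_init__(self):
        if self.significance_threshold_da <= 0:
            raise InputError("significance threshold must be > 0")
        if self.exchangeable_rule != "nterm1-noproline":
            raise InputError(f"unknown exchangeable-amide rule {self.exchangeable_rule!r}")


def centroid_neutral_mass(envelope: SpectrumEnvelope) -> float:
    """Intensity-weighted centroid of the envelope on the neutral-mass scale.

    Invariant to uniform intensity scaling.
    """
    total = envelope.intensity.sum()
    if total <= 0:
        raise InputError("zero total intensity")
    centroid_mz = float(np.dot(envelope.mz, envelope.intensity) / total)
    return envelope.charge * (centroid_mz - PROTON_MASS_DA)


def compute_uptake(
    deut: SpectrumEnvelope,
    undeut_ref: SpectrumEnvelope,
    peptide: PeptideRecord,
) -> UptakeMeasurement:
    """Centroid deuterium uptake relative to the undeuterated control.

    ``percent_d`` normalises to the peptide's theoretical maximum uptake;
    no back-exchange correction is applied, so values may slightly exceed
    [0, 100] under noise.
    """
    if deut.peptide_id != undeut_ref.peptide_id or deut.peptide_id != peptide.peptide_id:
        raise InputError(
            f"peptide mismatch: {deut.peptide_id!r} vs {undeut_ref.peptide_id!r} "
            f"vs {peptide.peptide_id!r}"
        )
    if peptide.max_uptake_da == 0:
        raise InputError(
            f"peptide {peptide.peptide_id} has no exchangeable amides; "
            "percent deuteration undefined"
        )
    uptake = centroid_neutral_mass(deut) - centroid_neutral_mass(undeut_ref)
    return UptakeMeasurement(
        peptide_id=deut.peptide_id,
        condition=deut.condition,
        timepoint_s=deut.timepoint_s,
        replicate=deut.replicate,
        uptake_da=uptake,
        percent_d=100.0 * uptake / peptide.max_uptake_da,
    )


def diff_uptake(
    cond_a: Iterable[UptakeMeasurement],
    cond_b: Iterable[UptakeMeasurement],
    cfg: HdxConfig | None = None,
    peptides: Optional[Mapping[str, PeptideRecord]] = None,
) -> pd.DataFrame:
    """Per-(peptide, timepoint) uptake difference ``mean(a) - mean(b)``.

    Replicates are averaged per key (SD carried for reporting).  A
    difference is flagged significant iff it strictly exceeds the
    threshold in magnitude (``|diff| > 0.4 Da`` by default).  Rows are
    ordered N- to C-terminally by peptide start (when a peptide table is
    given) then by timepoint.
    """
    cfg = cfg or HdxConfig()

    def collect(ms):
        d: dict[tuple[str, float], list[float]] = {}
        for m in ms:
            d.setdefault((m.peptide_id, m.timepoint_s), []).append(m.uptake_da)
        return d

    a, b = collect(cond_a), collect(cond_b)
    keys = sorted(set(a) & set(b))
    if not keys:
        raise InputError("conditions share no (peptide, timepoint) keys")
    rows = []
    for pep, t in keys:
        va, vb = a[(pep, t)], b[(pep, t)]
        diff = float(np.mean(va) - np.mean(vb))
        rows.append(
            {
                "peptide_id": pep,
                "timepoint_s": t,
                "mean_a": float(np.mean(va)),
                "mean_b": float(np.mean(vb)),
                "sd_a": float(np.std(va, ddof=1)) if len(va) > 1 else 0.0,
                "sd_b": float(np.std(vb, ddof=1)) if len(vb) > 1 else 0.0,
                "n_a": len(va),
                "n_b": len(vb),
                "diff_da": diff,
                "significant": abs(diff) > cfg.significance_threshold_da,
            }
        )
    df = pd.DataFrame(rows)
    if peptides:
        df["_start"] = df["peptide_id"].map(
            lambda p: peptides[p].start_res if p in peptides else np.inf
        )
        df = df.sort_values(["_start", "peptide_id", "timepoint_s"]).drop(columns="_start")
    else:
        df = df.sort_values(["peptide_id", "timepoint_s"])
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# bimodal deconvolution


def _gauss_area(m: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Unit-area Gaussian density."""
    return np.exp(-0.5 * ((m - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))


def _weighted_percentile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cw = cw / cw[-1]
    return float(np.interp(q, cw, x[order]))


def _fit_two_gauss(
    m: np.ndarray,
    y: np.ndarray,
    mu1_0: float,
    mu2_0: float,
    sigma0: float,
    a1_0: float,
    a2_0: float,
    sigma_bounds: tuple[float, float],
):
    span = m[-1] - m[0]

    def residual(p):
        mu1, mu2, logsig, a1, a2 = p
        sig = math.exp(logsig)
        return a1 * _gauss_area(m, mu1, sig) + a2 * _gauss_area(m, mu2, sig) - y

    lo = [m[0], m[0], math.log(sigma_bounds[0]), 0.0, 0.0]
    hi = [m[-1], m[-1], math.log(sigma_bounds[1]), np.inf, np.inf]
    p0 = [
        min(max(mu1_0, m[0]), m[-1]),
        min(max(mu2_0, m[0]), m[-1]),
        math.log(min(max(sigma0, sigma_bounds[0] * 1.001), sigma_bounds[1] * 0.999)),
        max(a1_0, 1e-12),
        max(a2_0, 1e-12),
    ]
    res = least_squares(residual, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, max_nfev=2000)
    mu1, mu2, logsig, a1, a2 = res.x
    return mu1, mu2, math.exp(logsig), a1, a2, float(np.sum(res.fun**2)), res.success, span


def fit_bimodal(
    envelope: SpectrumEnvelope,
    parsimony_rtol: float = 0.02,
    unresolved_sep_sigmas: float = 2.0,
) -> BimodalFit:
    """Decompose an envelope into two shared-width Gaussian subpopulations.

    The fit runs on the charge-deconvoluted (neutral-mass) axis from a
    small deterministic ladder of starting points: a percentile-based
    balanced start plus nearly-unimodal starts at either extreme.  The
    lowest-residual solution wins; solutions whose residual is within
    ``parsimony_rtol`` (relative) of the best are considered equivalent
    and the least-mixed one is preferred.  When the winning components
    are unresolved (separation at most ``unresolved_sep_sigmas`` shared
    widths) the envelope represents a single subpopulation, and rather
    than reporting an arbitrary split it is assigned wholly to the
    closed or open side according to whether its centroid lies in the
    lower or upper half of the recorded mass window (HDX spectra are
    acquired over the peptide's full deuteration range, so the window
    midpoint separates mostly-protected from mostly-exchanged).
    Components are relabelled after fitting so ``mu_low < mu_high``;
    ``f_open`` is the high-mass area fraction.
    """
    if len(envelope.mz) < 6:
        raise InsufficientDataError("bimodal fit needs at least 6 envelope points")
    m = envelope.neutral_mass
    y = envelope.intensity.astype(float)
    # scale-invariant fit: normalise to unit summed intensity
    y = y / y.sum()
    # convert summed intensities to a density so fitted a's are areas
    dm = float(np.median(np.diff(m)))
    y_dens = y / dm

    w = y / y.sum()
    mean = float(np.dot(m, w))
    sd = math.sqrt(max(float(np.dot((m - mean) ** 2, w)), 1e-12))
    q25 = _weighted_percentile(m, w, 0.25)
    q75 = _weighted_percentile(m, w, 0.75)
    total_area = 1.0  # after normalisation, Σ y·dm = 1
    mid = 0.5 * (q25 + q75)
    a_left = float(y[m <= mid].sum())
    a_right = total_area - a_left
    sigma0 = max(sd / 2, dm)
    span = m[-1] - m[0]
    sigma_bounds = (dm / 2, span)

    starts = [
        # balanced, percentile-seeded (the default initialisation)
        (q25, q75, sigma0, a_left, a_right),
        # nearly unimodal, low-mass dominant
        (mean, min(mean + 2 * sd, m[-1]), sd, 0.98 * total_area, 0.02 * total_area),
        # nearly unimodal, high-mass dominant
        (max(mean - 2 * sd, m[0]), mean, sd, 0.02 * total_area, 0.98 * total_area),
        # symmetric split about the mean
        (mean - sd, mean + sd, sigma0, 0.5, 0.5),
    ]
    fits = []
    any_converged = False
    for mu1_0, mu2_0, s0, a1_0, a2_0 in starts:
        mu1, mu2, sig, a1, a2, rss, ok, _ = _fit_two_gauss(
            m, y_dens, mu1_0, mu2_0, s0, a1_0, a2_0, sigma_bounds
        )
        if mu1 > mu2:
            mu1, mu2, a1, a2 = mu2, mu1, a2, a1
        at_bounds = sig <= sigma_bounds[0] * 1.01 or sig >= sigma_bounds[1] * 0.99
        fits.append((rss, mu1, mu2, sig, a1, a2, ok and not at_bounds))
        any_converged = any_converged or (ok and not at_bounds)

    rss_min = min(f[0] for f in fits)
    equivalent = [f for f in fits if f[0] <= rss_min * (1 + parsimony_rtol)]
    # prefer the least-mixed equivalent solution (parsimony)
    best = max(
        equivalent,
        key=lambda f: abs((f[5] / (f[4] + f[5]) if f[4] + f[5] > 0 else 0.5) - 0.5),
    )
    rss, mu_low, mu_high, sigma, area_low, area_high, ok = best
    if mu_high - mu_low <= unresolved_sep_sigmas * sigma:
        # unresolved: a single subpopulation, not a mixture
        mu1, sig1, a1, rss1 = _fit_one_gauss(m, y_dens)
        window_mid = 0.5 * (m[0] + m[-1])
        if mu1 <= window_mid:  # protected half of the window: all closed
            mu_low, mu_high = mu1, mu1 + 2 * sig1
            area_low, area_high = a1, 0.0
        else:  # exchanged half: all open
            mu_low, mu_high = mu1 - 2 * sig1, mu1
            area_low, area_high = 0.0, a1
        sigma, rss = sig1, rss1
    if mu_low == mu_high:
        mu_high = mu_low + 1e-9
    return BimodalFit(
        mu_low=float(mu_low),
        mu_high=float(mu_high),
        sigma=float(sigma),
        area_low=float(area_low),
        area_high=float(area_high),
        rss=float(rss),
        converged=bool(ok),
    )


def _fit_one_gauss(m: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    w = y / y.sum()
    mean = float(np.dot(m, w))
    sd = math.sqrt(max(float(np.dot((m - mean) ** 2, w)), 1e-12))
    dm = float(np.median(np.diff(m)))

    def residual(p):
        mu, logsig, a = p
        return a * _gauss_area(m, mu, math.exp(logsig)) - y

    res = least_squares(
        residual,
        [mean, math.log(max(sd, dm)), 1.0],
        xtol=1e-12,
        ftol=1e-12,
        max_nfev=1000,
    )
    mu, logsig, a = res.x
    return mu, math.exp(logsig), a, float(np.sum(res.fun**2))


def _aicc(n: int, rss: float, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def classify_bimodality(
    envelope: SpectrumEnvelope,
    min_separation_sigmas: float = 2.0,
    parsimony_rtol: float = 0.02,
) -> tuple[str, float]:
    """Classify an envelope as ``"unimodal"`` or ``"bimodal"``.

    Compares one- vs two-Gaussian fits by small-sample-corrected AIC; a
    bimodal call additionally requires the fitted means to be separated
    by more than ``min_separation_sigmas`` shared widths.  Returns the
    label and the AICc preference score (positive favours two components).
    """
    m = envelope.neutral_mass
    y = envelope.intensity / envelope.intensity.sum()
    dm = float(np.median(np.diff(m)))
    y_dens = y / dm
    _, _, _, rss1 = _fit_one_gauss(m, y_dens)
    two = fit_bimodal(envelope, parsimony_rtol=parsimony_rtol)
    n = len(m)
    score = _aicc(n, rss1, 4) - _aicc(n, two.rss, 6)
    separated = (two.mu_high - two.mu_low) > min_separation_sigmas * two.sigma
    label = "bimodal" if (score > 0 and separated) else "unimodal"
    return label, float(score)


def fit_transition_kinetics(
    series: Sequence[tuple[float, float]],
) -> Ex1Kinetics:
    """Fit first-order closed-to-open interconversion to an f_open time series.

    Model: ``f(t) = f_inf - (f_inf - f0) * exp(-k_open * t)`` with box
    constraints ``f0, f_inf in [0, 1]`` and ``k_open >= 0``.
    """
    if len(series) < 3:
        raise InsufficientDataError("kinetics fit needs at least 3 timepoints")
    t = np.array([s[0] for s in series], dtype=float)
    f = np.array([s[1] for s in series], dtype=float)
    if np.any((f < -1e-9) | (f > 1 + 1e-9)):
        raise InputError("f_open values must lie in [0, 1]")
    f = np.clip(f, 0.0, 1.0)

    def residual(p):
        k, f0, finf = p
        return finf - (finf - f0) * np.exp(-k * t) - f

    tpos = t[t > 0]
    k_inits = [1.0 / np.median(tpos), 1.0 / tpos.max(), 1.0 / tpos.min()] if len(tpos) else [1e-3]
    best = None
    for k0 in k_inits:
        res = least_squares(
            residual,
            [k0, float(np.clip(f[0], 0, 1)), float(np.clip(f[-1], 0, 1))],
            bounds=([0.0, 0.0, 0.0], [np.inf, 1.0, 1.0]),
            xtol=1e-15,
            ftol=1e-15,
            max_nfev=5000,
        )
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    rss, (k, f0, finf) = best
    return Ex1Kinetics(k_open=float(k), f0=float(f0), f_inf=float(finf), rss=rss)


def coverage_summary(
    peptides: Sequence[PeptideRecord],
    protein_sequence: str,
) -> tuple[int, float]:
    """Peptide count and percent of the protein's exchangeable amides covered.

    A peptide covers the exchangeable positions 2..n of its own span
    (non-proline, construct numbering); coverage is the union over
    peptides divided by the protein's own exchangeable-amide count.
    """
    n = len(protein_sequence)
    protein_exch = {
        i for i in range(2, n + 1) if protein_sequence[i - 1] != "P"
    }
    covered: set[int] = set()
    for pep in peptides:
        if pep.start_res < 1 or pep.end_res > n:
            raise InputError(
                f"peptide {pep.peptide_id} ({pep.start_res}-{pep.end_res}) "
                f"out of protein range 1-{n}"
            )
        for j, aa in enumerate(pep.sequence):
            pos = pep.start_res + j
            if j >= 1 and aa != "P":
                covered.add(pos)
    covered &= protein_exch
    pct = 100.0 * len(covered) / len(protein_exch) if protein_exch else 0.0
    return len(peptides), pct


# ---------------------------------------------------------------------------
# long-format CSV I/O (the interchange format of the pipeline)

ENVELOPE_COLUMNS = [
    "peptide_id",
    "condition",
    "timepoint_s",
    "replicate",
    "charge",
    "mz",
    "intensity",
]


def envelopes_to_frame(envelopes: Iterable[SpectrumEnvelope]) -> pd.DataFrame:
    rows = []
    for e in envelopes:
        for mz, inten in zip(e.mz, e.intensity):
            rows.append(
                (e.peptide_id, e.condition, e.timepoint_s, e.replicate, e.charge, mz, inten)
            )
    return pd.DataFrame(rows, columns=ENVELOPE_COLUMNS)


def frame_to_envelopes(df: pd.DataFrame) -> list[SpectrumEnvelope]:
    missing = set(ENVELOPE_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"envelope table missing columns: {sorted(missing)}")
    out = []
    keys = ["peptide_id", "condition", "timepoint_s", "replicate", "charge"]
    for (pid, cond, t, rep, z), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("mz")
        out.append(
            SpectrumEnvelope(
                peptide_id=str(pid),
                condition=str(cond),
                timepoint_s=float(t),
                replicate=int(rep),
                charge=int(z),
                mz=grp["mz"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
            )
        )
    return out


def read_envelope_csv(path: str | Path) -> list[SpectrumEnvelope]:
    return frame_to_envelopes(pd.read_csv(path))


def read_peptide_csv(path: str | Path) -> dict[str, PeptideRecord]:
    df = pd.read_csv(path)
    required = {"peptide_id", "sequence", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"peptide table missing columns: {sorted(missing)}")
    peptides = {}
    for _, row in df.iterrows():
        rec = PeptideRecord(
            peptide_id=str(row["peptide_id"]),
            sequence=str(row["sequence"]),
            start_res=int(row["start"]),
            end_res=int(row["end"]),
        )
        peptides[rec.peptide_id] = rec
    return peptides
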