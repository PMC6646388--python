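"""Rule-based validation of peptide detections in MRM chromatograms.

A peptide is called *detected* in a sample only when three criteria hold
across its technical replicates:

A. co-elution — every monitored transition reaches its apex within a
   small retention-time window (default 0.2 min max pairwise spread);
B. pattern fidelity — the mean dot-product (dotp) between observed
   transition areas and the reference intensity ratios exceeds 0.80
   (strict inequality);
C. reproducibility — the signal is present, above the noise floor, and
   co-eluting in *every* technical replicate.

When an unlabeled synthetic standard was spiked, a fourth gate applies:
the spiked run's total area must clearly exceed the endogenous one, the
endogenous pattern must match the standard's reference (dotp > 0.80),
and the endogenous and spiked retention times must agree within 3 min
(inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .proteome_io import ReferencePattern

REASON_MISSING_TRANSITION = "missing_transition"
REASON_NO_AREA_INCREASE = "no_area_increase"


@dataclass
class Thresholds:
    """Validation thresholds; defaults follow standard SRM review practice."""

    coelution_tolerance_min: float = 0.2
    dotp_threshold: float = 0.80        # strict: mean dotp must exceed this
    spikein_fold: float = 0.5           # (spiked - endog) must exceed fold*endog
    spikein_rt_tolerance_min: float = 3.0  # inclusive
    noise_floor_mads: float = 3.0
    sqrt_transform: bool = False
    smooth_width: int = 3


@dataclass
class TransitionTrace:
    fragment_label: str
    time_min: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_min.shape != self.intensity.shape:
            raise ValueError("time and intensity must align")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass
class PeakGroup:
    """All transition traces for one peptide in one run."""

    run_id: str
    peptide: str
    traces: list[TransitionTrace]
    technical_replicate_index: int = 0

    def __post_init__(self) -> None:
        if len(self.traces) < 2:
            raise ValueError("a peak group needs >=2 transitions")

    @property
    def fragment_labels(self) -> list[str]:
        return [t.fragment_label for t in self.traces]


@dataclass
class IntegratedTransition:
    fragment_label: str
    area: float          # intensity * seconds
    apex_rt: float       # minutes
    present: bool        # apex rises above the noise floor


@dataclass
class SpikeinRecord:
    area_ratio: float          # (spiked - endogenous) / endogenous
    rt_diff_min: float
    dotp_vs_standard: float
    passed: bool
    reasons: tuple[str, ...] = ()


@dataclass
class ValidationVerdict:
    peptide: str
    run_id: str
    coelution_pass: bool
    max_apex_spread_min: float
    dotp: float                 # mean over replicates
    dotp_pass: bool
    replicate_pass: bool
    spikein: SpikeinRecord | None = None
    detected: bool = False
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ok = self.coelution_pass and self.dotp_pass and self.replicate_pass
        if self.spikein is not None:
            ok = ok and self.spikein.passed
        self.detected = ok


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def integrate_traces(
    group: PeakGroup, thresholds: Thresholds | None = None
) -> list[IntegratedTransition]:
    """Trapezoidal area (intensity*seconds) and smoothed-apex RT per transition.

    Presence is decided against a robust noise floor: the smoothed maximum
    must exceed median + ``noise_floor_mads`` * 1.4826 * MAD of the raw
    trace. Flat or empty traces are absent, not errors.
    """
    thresholds = thresholds or Thresholds()
    out = []
    for tr in group.traces:
        if tr.time_min.size < 3:
            raise ValueError(
                f"trace {tr.fragment_label} of {group.peptide} has fewer than 3 points"
            )
        smooth = _moving_average(tr.intensity, thresholds.smooth_width)
        apex_idx = int(np.argmax(smooth))
        area = float(np.trapezoid(tr.intensity, tr.time_min * 60.0))
        med = float(np.median(tr.intensity))
        mad = float(np.median(np.abs(tr.intensity - med)))
        floor = med + thresholds.noise_floor_mads * 1.4826 * mad
        present = bool(smooth[apex_idx] > floor and area > 0)
        out.append(
            IntegratedTransition(
                fragment_label=tr.fragment_label,
                area=area,
                apex_rt=float(tr.time_min[apex_idx]),
                present=present,
            )
        )
    return out


def check_coelution(
    integrated: list[IntegratedTransition], tolerance_min: float = 0.2
) -> tuple[bool, float, tuple[str, ...]]:
    """Criterion A: max pairwise apex spread within tolerance, all present."""
    if len(integrated) < 2:
        raise ValueError("co-elution needs >=2 transitions")
    missing = [t.fragment_label for t in integrated if not t.present]
    apexes = [t.apex_rt for t in integrated if t.present]
    spread = float(max(apexes) - min(apexes)) if len(apexes) >= 2 else float("inf")
    if missing:
        return False, spread, (REASON_MISSING_TRANSITION,)
    return spread <= tolerance_min, spread, ()


def dotp(
    observed: np.ndarray, reference: np.ndarray, sqrt_transform: bool = False
) -> float:
    """Normalized dot product of two nonnegative intensity vectors, in [0, 1].

    Scale-invariant; 1 iff the vectors are proportional. A zero observed
    vector yields 0 with a warning rather than an error.
    """
    a = np.asarray(observed, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("observed and reference must share the transition set")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("dotp is defined on nonnegative vectors")
    if sqrt_transform:
        a, b = np.sqrt(a), np.sqrt(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0:
        warnings.warn("zero observed intensity vector; dotp defined as 0", stacklevel=2)
        return 0.0
    if nb == 0:
        raise ValueError("reference vector is all zero")
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def _ordered_areas(
    integrated: list[IntegratedTransition], reference: ReferencePattern
) -> np.ndarray:
    by_label = {t.fragment_label: t for t in integrated}
    missing = [l for l in reference.fragment_labels if l not in by_label]
    if missing:
        raise ValueError(f"peak group lacks transition(s) {missing} of the reference")
    return np.array([by_label[l].area for l in reference.fragment_labels])


def validate_detection(
    replicate_groups: list[PeakGroup],
    reference: ReferencePattern,
    thresholds: Thresholds | None = None,
    spikein: SpikeinRecord | None = None,
) -> ValidationVerdict:
    """Apply criteria A-C (and the optional spike-in gate) to one peptide.

    ``replicate_groups`` are the technical replicates of one sample. dotp
    is averaged arithmetically across replicates; criterion C demands
    presence *and* co-elution in every replicate.
    """
    if not replicate_groups:
        raise ValueError("at least one replicate required")
    thresholds = thresholds or Thresholds()
    peptide = replicate_groups[0].peptide
    if reference.peptide != peptide:
        raise ValueError(f"reference is for {reference.peptide}, groups for {peptide}")

    dotps, spreads, reasons = [], [], set()
    coelution_all, present_all = True, True
    for group in replicate_groups:
        integ = integrate_traces(group, thresholds)
        ok, spread, why = check_coelution(integ, thresholds.coelution_tolerance_min)
        coelution_all &= ok
        reasons.update(why)
        spreads.append(spread)
        if not all(t.present for t in integ):
            present_all = False
        areas = _ordered_areas(integ, reference)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dotps.append(dotp(areas, reference.ratios, thresholds.sqrt_transform))
    mean_dotp = float(np.mean(dotps))
    finite = [s for s in spreads if np.isfinite(s)]
    return ValidationVerdict(
        peptide=peptide,
        run_id=replicate_groups[0].run_id,
        coelution_pass=coelution_all,
        max_apex_spread_min=float(max(finite)) if finite else float("inf"),
        dotp=mean_dotp,
        dotp_pass=mean_dotp > thresholds.dotp_threshold,
        replicate_pass=present_all and coelution_all,
        spikein=spikein,
        reasons=tuple(sorted(reasons)),
    )


def spikein_check(
    endogenous: PeakGroup,
    spiked: PeakGroup,
    standard_reference: ReferencePattern,
    thresholds: Thresholds | None = None,
) -> SpikeinRecord:
    """Spike-in standard gate: area increase, pattern match, RT agreement.

    Passing requires (spiked - endogenous) total area > fold * endogenous,
    dotp of the endogenous pattern against the standard's reference
    > 0.80, and |RT(endogenous) - RT(spiked)| <= 3 min inclusive.
    """
    thresholds = thresholds or Thresholds()
    if endogenous.fragment_labels != spiked.fragment_labels:
        raise ValueError("endogenous and spiked runs must monitor identical transitions")
    integ_e = integrate_traces(endogenous, thresholds)
    integ_s = integrate_traces(spiked, thresholds)
    area_e = sum(t.area for t in integ_e)
    area_s = sum(t.area for t in integ_s)
    reasons: list[str] = []
    if area_s <= area_e:
        reasons.append(REASON_NO_AREA_INCREASE)
        ratio = (area_s - area_e) / area_e if area_e > 0 else float("-inf")
    else:
        ratio = (area_s - area_e) / area_e if area_e > 0 else float("inf")
    rt_e = float(np.median([t.apex_rt for t in integ_e if t.present]))
    rt_s = float(np.median([t.apex_rt for t in integ_s if t.present]))
    rt_diff = abs(rt_e - rt_s)
    areas_e = _ordered_areas(integ_e, standard_reference)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = dotp(areas_e, standard_reference.ratios, thresholds.sqrt_transform)
    passed = (
        not reasons
        and ratio > thresholds.spikein_fold
        and d > thresholds.dotp_threshold
        and rt_diff <= thresholds.spikein_rt_tolerance_min
    )
    return SpikeinRecord(
        area_ratio=ratio,
        rt_diff_min=rt_diff,
        dotp_vs_standard=d,
        passed=passed,
        reasons=tuple(reasons),
    )
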