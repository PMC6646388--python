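"""Synthetic proteomes and MRM chromatograms with known ground truth.

Every stage of the pipeline can be exercised without external data:

* ``simulate_proteomes`` draws random protein sequences and plants chosen
  peptides verbatim (flanked so they are clean tryptic products) into
  selected proteomes, so each specificity tier has known-truth members.
* ``simulate_peak_group`` renders one peptide's transitions as Gaussian
  elution peaks whose amplitudes follow the reference intensity ratios,
  with a shared apex retention time, optional per-transition RT jitter
  and additive noise. Decoy modes corrupt a group in controlled ways:
  ``ratio_permute`` cyclically shifts the amplitude pattern (driving dotp
  well below 0.80 for the default skewed pattern), ``rt_shift`` moves the
  whole group in time, and ``dropout`` silences transitions.

All randomness flows through one seeded ``numpy.random.Generator``; a
fixed seed reproduces every sequence and trace byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .proteome_io import Category, Proteome, ReferencePattern
from .validation import PeakGroup, TransitionTrace

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimConfig:
    """Knobs of the synthetic world; defaults give clean, detectable data."""

    seed: int = 0
    n_proteins: int = 30               # per proteome
    protein_length_mean: float = 300.0
    protein_length_sd: float = 80.0
    amplitude_range: tuple[float, float] = (1e4, 1e6)
    sigma_rt_min: float = 0.05         # chromatographic peak width (sigma)
    rt_jitter_sd_min: float = 0.005    # per-transition apex jitter
    sampling_interval_s: float = 1.0
    noise_model: str = "gaussian_relative"  # or "poisson"
    noise_scale: float = 0.01
    baseline: float = 50.0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.sigma_rt_min <= 0:
            raise ValueError("sigma_rt_min must be positive")
        if self.noise_model not in ("gaussian_relative", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass(frozen=True)
class PlantSpec:
    """Plant ``peptide`` verbatim into each listed proteome."""

    peptide: str
    proteome_ids: tuple[str, ...]


@dataclass
class TruthRow:
    peptide: str
    proteome_ids: tuple[str, ...]
    tier: str  # expected specificity tier


def _random_protein(rng: np.random.Generator, config: SimConfig) -> str:
    n = max(30, int(rng.normal(config.protein_length_mean, config.protein_length_sd)))
    return "".join(rng.choice(list(RESIDUES), size=n))


def _plant(sequence: str, peptide: str, rng: np.random.Generator) -> str:
    """Insert ``peptide`` so that it digests out as a clean tryptic product.

    The insert is preceded by an R (cleavage before the peptide) and, when
    the peptide does not already end in K/R, followed by an R; the residue
    after the insertion point must not be P (which would suppress the
    trailing cleavage).
    """
    pos = int(rng.integers(1, max(2, len(sequence) - 1)))
    tail = sequence[pos:]
    if tail.startswith("P"):
        tail = "A" + tail[1:]
    insert = "R" + peptide + ("" if peptide[-1] in "KR" else "R")
    return sequence[:pos] + insert + tail


def simulate_proteomes(
    config: SimConfig,
    layout: dict[str, Category] | None = None,
    planted: list[PlantSpec] = (),
) -> tuple[list[Proteome], list[TruthRow]]:
    """Build a labeled proteome registry with planted specificity truth.

    ``layout`` maps proteome id -> category (default: three targets, two
    related organohalide respirers, two unrelated). Returns the proteome
    list and a truth table giving each planted peptide's expected tier,
    derived purely from the categories it was planted into.
    """
    rng = np.random.default_rng(config.seed)
    if layout is None:
        layout = {
            "T1": Category.TARGET,
            "T2": Category.TARGET,
            "T3": Category.TARGET,
            "R1": Category.RELATED_OHRB,
            "R2": Category.RELATED_OHRB,
            "O1": Category.OTHER,
            "O2": Category.OTHER,
        }
    sequences: dict[str, list[str]] = {
        pid: [_random_protein(rng, config) for _ in range(config.n_proteins)]
        for pid in layout
    }
    truth: list[TruthRow] = []
    for spec in planted:
        bad = set(spec.peptide) - set(RESIDUES)
        if bad:
            raise ValueError(f"planted peptide {spec.peptide!r} has illegal letters {sorted(bad)}")
        cats = set()
        for pid in spec.proteome_ids:
            if pid not in sequences:
                raise ValueError(f"unknown proteome id {pid!r}")
            idx = int(rng.integers(0, config.n_proteins))
            sequences[pid][idx] = _plant(sequences[pid][idx], spec.peptide, rng)
            cats.add(layout[pid])
        if Category.OTHER in cats:
            tier = "non_specific"
        elif Category.RELATED_OHRB in cats:
            tier = "semi_specific"
        else:
            tier = "specific"
        truth.append(TruthRow(spec.peptide, tuple(spec.proteome_ids), tier))
    proteomes = [
        Proteome(
            id=pid,
            taxon_name=f"synthetic organism {pid}",
            category=cat,
            proteins=[(f"{pid}_p{i:03d}", s) for i, s in enumerate(sequences[pid])],
        )
        for pid, cat in layout.items()
    ]
    return proteomes, truth


# ---------------------------------------------------------------------------
# chromatogram simulation
# ---------------------------------------------------------------------------


def skewed_reference(
    peptide: str,
    fragment_labels: list[str],
    reference_rt: float,
    ratio: float = 0.5,
) -> ReferencePattern:
    """Geometric intensity pattern (1, r, r^2, ...), normalized.

    Chosen because any cyclic shift of a geometric pattern has a closed-
    form dotp against the original well below 0.80 for r=0.5 and >=3
    transitions, so ratio-permuted decoys fail criterion B by construction.
    """
    ratios = ratio ** np.arange(len(fragment_labels))
    return ReferencePattern(
        peptide=peptide,
        fragment_labels=list(fragment_labels),
        ratios=ratios,
        reference_rt=reference_rt,
    )


def permuted_dotp(ratios: np.ndarray, shift: int = 1) -> float:
    """Closed-form dotp between a ratio vector and its cyclic shift."""
    a = np.asarray(ratios, float)
    b = np.roll(a, shift)
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def simulate_peak_group(
    reference: ReferencePattern,
    config: SimConfig,
    rng: np.random.Generator,
    run_id: str = "sim",
    decoy_mode: str | None = None,
    dropout_k: int = 1,
    rt_shift_min: float = 5.0,
    amplitude: float | None = None,
    replicate_index: int = 0,
) -> PeakGroup:
    """Render one peptide's transition traces around the reference RT.

    ``decoy_mode`` is ``None`` (faithful), ``"ratio_permute"``,
    ``"rt_shift"``, ``"dropout"`` or ``"absent"`` (baseline noise only).
    """
    if decoy_mode not in (None, "ratio_permute", "rt_shift", "dropout", "absent"):
        raise ValueError(f"unknown decoy mode {decoy_mode!r}")
    sigma = config.sigma_rt_min
    apex = reference.reference_rt
    ratios = reference.ratios.copy()
    if decoy_mode == "ratio_permute":
        ratios = np.roll(ratios, 1)
    if decoy_mode == "rt_shift":
        apex = apex + rt_shift_min
    if amplitude is None:
        lo, hi = config.amplitude_range
        amplitude = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    drop: set[int] = set()
    if decoy_mode == "dropout":
        drop = set(rng.choice(len(ratios), size=min(dropout_k, len(ratios) - 1), replace=False))
    elif decoy_mode == "absent":
        drop = set(range(len(ratios)))

    dt = config.sampling_interval_s / 60.0
    half_window = 6.0 * sigma + 0.1
    t = np.arange(apex - half_window, apex + half_window + dt / 2, dt)
    traces = []
    for i, (label, frac) in enumerate(zip(reference.fragment_labels, ratios)):
        jitter = rng.normal(0.0, config.rt_jitter_sd_min) if config.rt_jitter_sd_min > 0 else 0.0
        amp = 0.0 if i in drop else amplitude * frac
        signal = amp * np.exp(-0.5 * ((t - apex - jitter) / sigma) ** 2) + config.baseline
        if config.noise_scale > 0:
            if config.noise_model == "gaussian_relative":
                noise = rng.normal(0.0, 1.0, t.size) * (
                    config.noise_scale * signal + 0.05 * config.baseline
                )
                signal = signal + noise
            else:
                signal = rng.poisson(np.maximum(signal, 0.0)).astype(float)
        traces.append(
            TransitionTrace(
                fragment_label=label,
                time_min=t,
                intensity=np.clip(signal, 0.0, None),
            )
        )
    return PeakGroup(
        run_id=run_id,
        peptide=reference.peptide,
        traces=traces,
        technical_replicate_index=replicate_index,
    )


def detection_scenario(
    n_targeted: int,
    n_detectable: int,
    config: SimConfig,
    n_transitions: int = 5,
) -> tuple[dict[str, ReferencePattern], dict[str, list[PeakGroup]], dict[str, bool]]:
    """A panel of ``n_targeted`` peptides of which ``n_detectable`` yield
    faithful replicate signals; the rest are absent or decoy-corrupted.

    Returns (references, replicate groups per peptide, truth map
    peptide -> should_be_detected).
    """
    if not 0 <= n_detectable <= n_targeted:
        raise ValueError("need 0 <= n_detectable <= n_targeted")
    rng = np.random.default_rng(config.seed)
    references: dict[str, ReferencePattern] = {}
    groups: dict[str, list[PeakGroup]] = {}
    truth: dict[str, bool] = {}
    # every decoy flavor here fails at least one of criteria A-C
    decoy_cycle = ["absent", "ratio_permute", "dropout"]
    for i in range(n_targeted):
        pep = f"PEP{i:03d}SIMK"
        labels = [f"y{j}" for j in range(3, 3 + n_transitions)]
        rt = 10.0 + 0.8 * i
        ref = skewed_reference(pep, labels, rt)
        references[pep] = ref
        detectable = i < n_detectable
        truth[pep] = detectable
        mode = None if detectable else decoy_cycle[i % len(decoy_cycle)]
        groups[pep] = [
            simulate_peak_group(
                ref, config, rng, run_id=f"rep{r}", decoy_mode=mode, replicate_index=r
            )
            for r in range(config.n_replicates)
        ]
    return references, groups, truth
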