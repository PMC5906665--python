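"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study design this package targets: positive-mode
MS/MS spectra of glycosylated flavonoids following the diagnostic
fragmentation rules (whole-residue losses for O-glycosides, cross-ring
partial losses for C-glycosides, acyl marker ions), two-group intensity
matrices with three biological replicates per group and a planted informative
fraction, negative-binomial count tables with planted differential genes, and
qPCR Ct tables with a planted induction.  Every generator is a pure function
of (config, seed).
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import (
    ACYL_MARKER_MZ,
    ACYL_MASS,
    C_PARTIAL,
    SUGAR_MASS,
    WATER,
    Aglycone,
    Annotation,
    ModificationEvent,
    _classify_events,
    default_aglycone_dict,
    isobar_group,
)
from .chemometrics import IntensityMatrix
from .spectra import Peak, Spectrum

__all__ = [
    "TrueStructure",
    "SimulationConfig",
    "enumerate_structures",
    "structure_id",
    "spectrum_from_structure",
    "structure_recovered",
    "make_two_group_matrix",
    "make_timecourse_matrix",
    "make_count_table",
    "make_qpcr_table",
]


@dataclass(frozen=True)
class TrueStructure:
    """A ground-truth glycosylflavonoid: aglycone + ordered modification events."""

    aglycone: Aglycone
    events: tuple[ModificationEvent, ...]

    @property
    def expected_precursor(self) -> float:
        return self.aglycone.protonated_mz + sum(e.exact_mass for e in self.events)

    @property
    def glyco_class(self) -> str:
        return _classify_events(self.events)


@dataclass(frozen=True)
class SimulationConfig:
    """Defaults mirror the emulated study: ~1000 signals, 10% informative
    features at a 2-sd effect, 3 replicates per group, mild log-normal noise."""

    seed: int = 0
    n_features: int = 1000
    frac_informative: float = 0.1
    effect_sd: float = 2.0
    lognormal_sd: float = 0.25
    mass_jitter_ppm: float = 0.0
    decoy_peaks: int = 0
    fragment_tol_da: float = 0.5
    nb_dispersion: float = 0.1
    ct_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.frac_informative <= 1:
            raise ValueError("frac_informative must be in [0, 1]")
        for name in ("n_features", "lognormal_sd", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mass_jitter_ppm < 0 or self.decoy_peaks < 0 or self.effect_sd < 0:
            raise ValueError("noise parameters must be non-negative")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def enumerate_structures(
    dictionary: Sequence[Aglycone] | None = None,
    sugars_c: Sequence[str] = ("hexose", "pentose"),
    sugars_o: Sequence[str] = ("hexose",),
    acyls: Sequence[str] = ("malonyl", "feruloyl", "coumaroyl"),
) -> list[TrueStructure]:
    """The full structure grid: every glycosylation class crossed with every
    aglycone, sugar and acyl choice, deduplicated.

    The default spaces mirror the emulated chemistry: pentoses occur
    C-linked, O-glycosides are hexosides (possibly malonyl/feruloyl/
    coumaroyl-acylated).  With one aglycone, hexose on both sides and no
    acyls the grid is exactly the five unacylated classes (bare, O-mono,
    C-mono, di-C,C, C,O-di).
    """
    dictionary = default_aglycone_dict() if dictionary is None else list(dictionary)
    if not dictionary:
        raise ValueError("empty aglycone dictionary")
    for u in (*sugars_c, *sugars_o):
        if u not in SUGAR_MASS:
            raise ValueError(f"unknown sugar {u!r}")
    for a in acyls:
        if a not in ACYL_MASS:
            raise ValueError(f"unknown acyl {a!r}")
    out: list[TrueStructure] = []
    seen: set[tuple[str, tuple[ModificationEvent, ...]]] = set()

    def add(agl: Aglycone, events: Sequence[ModificationEvent]) -> None:
        key = (agl.name, tuple(sorted(events, key=lambda e: (e.linkage, e.unit, e.acyl))))
        if key not in seen:
            seen.add(key)
            out.append(TrueStructure(agl, key[1]))

    for agl in dictionary:
        add(agl, ())
        for u in sugars_o:
            add(agl, (ModificationEvent("O", u),))
            for a in acyls:
                add(agl, (ModificationEvent("O", u, a),))
        for u in sugars_c:
            add(agl, (ModificationEvent("C", u),))
        for u1, u2 in itertools.combinations_with_replacement(sugars_c, 2):
            add(agl, (ModificationEvent("C", u1), ModificationEvent("C", u2)))
        for uc, uo in itertools.product(sugars_c, sugars_o):
            add(agl, (ModificationEvent("C", uc), ModificationEvent("O", uo)))
            for a in acyls:
                add(agl, (ModificationEvent("C", uc), ModificationEvent("O", uo, a)))
    return out


def structure_id(t: TrueStructure) -> str:
    """Stable unique id for a ground-truth structure."""
    events = ",".join(f"{e.linkage}:{e.unit}:{e.acyl}" for e in t.events) or "bare"
    return f"synthetic::{t.aglycone.name}::{events}"


def _true_fragments(t: TrueStructure) -> list[float]:
    """Noise-free diagnostic fragment m/z values implied by the rules."""
    precursor = t.expected_precursor
    o_units = [e for e in t.events if e.linkage == "O"]
    c_units = [e for e in t.events if e.linkage == "C"]
    frags: list[float] = []
    if o_units:
        # stepwise whole losses of every non-empty O-unit subset; the full
        # loss exposes the C-core (or the aglycone ion when no C unit)
        for r in range(1, len(o_units) + 1):
            for combo in set(itertools.combinations(range(len(o_units)), r)):
                frags.append(precursor - sum(o_units[i].exact_mass for i in combo))
        if not c_units:
            # the free aglycone ion appears only when no sugar is C-linked
            frags.append(t.aglycone.protonated_mz)
    core = t.aglycone.protonated_mz + sum(e.exact_mass for e in c_units)
    for e in c_units:
        for exact in C_PARTIAL[e.unit].values():
            frags.append(precursor - exact)
            if o_units:
                frags.append(core - exact)
    if len(c_units) == 2:
        # both C sugars fragment simultaneously: combined pairwise losses
        for x1 in C_PARTIAL[c_units[0].unit].values():
            for x2 in C_PARTIAL[c_units[1].unit].values():
                frags.append(precursor - (x1 + x2))
    if c_units:
        frags.append(precursor - WATER)
    for e in t.events:
        if e.acyl in ACYL_MARKER_MZ:
            frags.append(ACYL_MARKER_MZ[e.acyl])
    # deduplicate to printed precision
    uniq = sorted({round(f, 4) for f in frags if f > 50.0})
    return uniq


def spectrum_from_structure(
    t: TrueStructure, cfg: SimulationConfig | None = None, spectrum_id: str | None = None
) -> Spectrum:
    """Generate the MS/MS spectrum a structure predicts.

    O-linked units produce the aglycone ion and stepwise whole-unit losses;
    C-linked units produce cross-ring partial losses (from the precursor and
    from the O-stripped core) plus a water loss; feruloyl and coumaroyl give
    their marker ions.  All m/z values receive seeded Gaussian ppm jitter and
    uniformly placed decoy peaks are added, never within twice the fragment
    tolerance of a true diagnostic ion.
    """
    cfg = cfg or SimulationConfig()
    # stable per-structure stream (string hashes are process-salted)
    key = f"{t.aglycone.name}|" + "|".join(f"{e.linkage}{e.unit}{e.acyl}" for e in t.events)
    rng = cfg.rng(stream=zlib.crc32(key.encode()))
    true_frags = _true_fragments(t)
    precursor = t.expected_precursor

    def jitter(mz: float) -> float:
        if cfg.mass_jitter_ppm <= 0:
            return mz
        return mz * (1.0 + rng.normal(0.0, cfg.mass_jitter_ppm) * 1e-6)

    peaks = [Peak(jitter(mz), intensity=float(rng.uniform(0.2, 1.0)) if cfg.mass_jitter_ppm > 0 else 1.0)
             for mz in true_frags]
    guard = 2.0 * cfg.fragment_tol_da
    n_decoys = 0
    attempts = 0
    while n_decoys < cfg.decoy_peaks and attempts < 1000:
        attempts += 1
        mz = float(rng.uniform(50.0, precursor))
        if all(abs(mz - f) > guard for f in true_frags + [precursor]):
            peaks.append(Peak(mz, intensity=float(rng.uniform(0.05, 0.3))))
            n_decoys += 1
    sid = spectrum_id or structure_id(t)
    return Spectrum(id=sid, precursor_mz=jitter(precursor), rt_min=float(rng.uniform(1, 15)),
                    peaks=tuple(peaks))


def structure_recovered(
    t: TrueStructure, ann: Annotation, dictionary: Sequence[Aglycone] | None = None
) -> bool:
    """Whether an annotation matches the ground truth: same class, same event
    multiset, aglycone correct up to its mass-isobar group."""
    dictionary = default_aglycone_dict() if dictionary is None else list(dictionary)
    if ann.glyco_class != t.glyco_class:
        return False
    truth_events = tuple(sorted(t.events, key=lambda e: (e.linkage, e.unit, e.acyl)))
    if ann.events != truth_events:
        return False
    if not ann.aglycone_candidates:
        return not t.events
    isobars = isobar_group(t.aglycone, dictionary)
    return any(c.name in isobars for c in ann.aglycone_candidates)


def make_two_group_matrix(
    cfg: SimulationConfig | None = None, n_per_group: int = 3
) -> tuple[IntensityMatrix, list[str]]:
    """Two-group log-normal intensity matrix with a planted informative
    fraction; returns (matrix, informative feature ids).

    Group-2 (treated) log-intensities of informative features are shifted by
    ``effect_sd`` within-group standard deviations.
    """
    cfg = cfg or SimulationConfig()
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = cfg.rng(stream=1)
    p = cfg.n_features
    n = 2 * n_per_group
    baseline = rng.normal(loc=10.0, scale=1.5, size=p)
    log_x = baseline[None, :] + rng.normal(0.0, cfg.lognormal_sd, size=(n, p))
    n_inf = int(round(cfg.frac_informative * p))
    informative = rng.choice(p, size=n_inf, replace=False)
    shift = cfg.effect_sd * cfg.lognormal_sd
    signs = rng.choice([-1.0, 1.0], size=n_inf)
    log_x[n_per_group:, informative] += shift * signs
    feature_ids = tuple(f"feat{i:04d}" for i in range(p))
    m = IntensityMatrix(
        values=np.exp(log_x),
        sample_ids=tuple(
            [f"control_r{i+1}" for i in range(n_per_group)]
            + [f"uvb_r{i+1}" for i in range(n_per_group)]
        ),
        feature_ids=feature_ids,
        group=tuple(["control"] * n_per_group + ["uvb"] * n_per_group),
    )
    return m, [feature_ids[i] for i in sorted(informative.tolist())]


def make_timecourse_matrix(
    cfg: SimulationConfig | None = None,
    n_per_group: int = 3,
    time_points: Sequence[float] = (12.0, 24.0, 48.0, 96.0),
    planted_fc: dict[str, dict[float, float]] | None = None,
    n_features: int | None = None,
) -> IntensityMatrix:
    """Treated/control matrix over a time course with planted linear fold
    changes per (feature, time); unplanted cells have fold change 1."""
    cfg = cfg or SimulationConfig()
    rng = cfg.rng(stream=2)
    p = n_features if n_features is not None else min(cfg.n_features, 50)
    feature_ids = tuple(f"met{i:03d}" for i in range(p))
    planted = planted_fc or {}
    rows, sample_ids, groups, times = [], [], [], []
    baseline = rng.normal(10.0, 1.0, size=p)
    for t in time_points:
        for grp in ("control", "uvb"):
            for r in range(n_per_group):
                log_x = baseline + rng.normal(0.0, cfg.lognormal_sd, size=p)
                if grp == "uvb":
                    for fid, by_time in planted.items():
                        if t in by_time:
                            log_x[feature_ids.index(fid)] += np.log(by_time[t])
                rows.append(np.exp(log_x))
                sample_ids.append(f"{grp}_{t:g}h_r{r+1}")
                groups.append(grp)
                times.append(t)
    return IntensityMatrix(np.array(rows), tuple(sample_ids), feature_ids,
                           tuple(groups), tuple(times))


def make_count_table(
    cfg: SimulationConfig | None = None,
    n_genes: int = 2000,
    n_de: int = 100,
    lfc: float = 2.0,
    n_reps: int = 3,
    mean_length_bp: int = 1500,
) -> dict:
    """Negative-binomial count table with *n_de* planted differential genes.

    Returns a dict with the counts DataFrame (control/treated replicates),
    per-gene lengths, a per-gene stats frame (observed log2fc and a
    negative-binomial Wald p-value computed at the generator's known
    dispersion), and the set of planted gene ids.
    """
    cfg = cfg or SimulationConfig()
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    rng = cfg.rng(stream=3)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    lengths = rng.integers(200, 2 * mean_length_bp, size=n_genes)
    base_mu = np.exp(rng.normal(np.log(100.0), 1.0, size=n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    mu_tr = base_mu.copy()
    mu_tr[de_idx] *= 2.0**lfc
    phi = cfg.nb_dispersion
    nb_n = 1.0 / phi

    def draw(mu: np.ndarray) -> np.ndarray:
        pr = nb_n / (nb_n + mu)
        return rng.negative_binomial(nb_n, pr[:, None], size=(n_genes, n_reps))

    counts_ctl = draw(base_mu)
    counts_tr = draw(mu_tr)
    counts = pd.DataFrame(
        np.hstack([counts_ctl, counts_tr]),
        index=gene_ids,
        columns=[f"control_r{i+1}" for i in range(n_reps)]
        + [f"treated_r{i+1}" for i in range(n_reps)],
    )
    # observed per-gene statistics on normalized log counts; median-of-ratios
    # size factors avoid the composition bias that total-count scaling
    # introduces when a planted fraction is regulated in one direction
    raw = counts.to_numpy().astype(float)
    with np.errstate(divide="ignore"):
        log_geo = np.log(raw).mean(axis=1)
    usable = np.isfinite(log_geo)
    size = np.exp(np.median(np.log(raw[usable]) - log_geo[usable, None], axis=0))
    cpm = raw / size[None, :]
    mean_ctl = cpm[:, :n_reps].mean(axis=1)
    mean_tr = cpm[:, n_reps:].mean(axis=1)
    log2fc = np.log2((mean_tr + 0.5) / (mean_ctl + 0.5))
    # Wald test on the log-mean difference; Var(log mu_hat) ~ (1/mu + phi)/n
    # with the generator's own dispersion phi (ground-truth statistics)
    from scipy import stats as _st

    var = ((1.0 / np.maximum(mean_tr, 0.5) + phi)
           + (1.0 / np.maximum(mean_ctl, 0.5) + phi)) / n_reps
    z = np.log(np.maximum(mean_tr, 0.5) / np.maximum(mean_ctl, 0.5)) / np.sqrt(var)
    pvalues = 2.0 * _st.norm.sf(np.abs(z))
    stats = pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": log2fc, "pvalue": pvalues}
    )
    return {
        "counts": counts,
        "length_bp": pd.Series(lengths, index=gene_ids, name="length_bp"),
        "stats": stats,
        "true_de": {gene_ids[i] for i in sorted(de_idx.tolist())},
    }


def make_qpcr_table(
    cfg: SimulationConfig | None = None, true_fold: float = 8.0, n_reps: int = 3
) -> pd.DataFrame:
    """qPCR Ct table with a planted induction.

    The reference gene Ct is constant; the target Ct drops by log2(true_fold)
    in treated samples; Gaussian Ct noise (sd ``ct_noise_sd``) is added to the
    target channel.
    """
    cfg = cfg or SimulationConfig()
    if true_fold <= 0:
        raise ValueError("true_fold must be positive")
    rng = cfg.rng(stream=4)
    ref_ct = 20.0
    ctl_target = 25.0
    rows = []
    for cond in ("control", "treated"):
        target = ctl_target - (np.log2(true_fold) if cond == "treated" else 0.0)
        for r in range(n_reps):
            noise = rng.normal(0.0, cfg.ct_noise_sd) if cfg.ct_noise_sd > 0 else 0.0
            rows.append(
                {"sample": f"{cond}_r{r+1}", "condition": cond,
                 "ct_target": target + noise, "ct_reference": ref_ct}
            )
    return pd.DataFrame(rows)
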