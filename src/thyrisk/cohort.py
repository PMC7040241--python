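"""Synthetic cohorts of cytologically indeterminate thyroid nodules.

The generator emulates the statistical structure of a surgical pilot cohort of
indeterminate (Bethesda III/IV) nodules: about 47 patients, roughly 60%
malignancy, a histology mix dominated by papillary carcinoma, and
histology-conditional somatic alteration spectra (BRAF V600E in classic and
micro PTC, RAS hotspots in follicular-variant PTC / poorly differentiated /
Hürthle-cell carcinoma, RET alterations in medullary carcinoma, PAX8-PPARG
fusion in NIFTP, sparse RAS/GNAS/ESR1/ATM/TET2 variants in benign adenomas),
together with malignancy-conditional ATA ultrasound patterns.

Alteration spectra are categorical over alteration *sets*: each nodule draws
one event from its histology's distribution, where an event can carry several
co-occurring alterations (multi-hit Hürthle profiles, BRAF+TERT) and the
unassigned remainder mass means "panel-negative". This keeps published
marginal frequencies exactly calibrated in expectation while still modelling
co-occurrence.

Randomness comes from a single seeded stream; each nodule consumes exactly
four uniforms in a fixed, documented order (malignancy, histology, ultrasound
pattern, alteration event), so adding config fields can never silently
reorder existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .genomics import GenomicAlteration, WeightTable, compute_xgc, default_weight_table
from .risk import Truth, XGC_CUTOFF, TRS_CUTOFF, XUS_CUTOFF, ge
from .ultrasound import AtaPattern, xus_from_pattern


class Histology(str, Enum):
    PTC = "PTC"                        # classic papillary carcinoma
    MICRO_PTC = "MICRO_PTC"            # papillary microcarcinoma within the index nodule
    PTCFV = "PTCFV"                    # follicular-variant papillary carcinoma
    NIFTP = "NIFTP"                    # counted as carcinoma for truth labelling
    HTC = "HTC"                        # Hürthle-cell carcinoma
    PDTC = "PDTC"                      # poorly differentiated carcinoma
    MTC = "MTC"                        # medullary carcinoma
    FOLLICULAR_ADENOMA = "FOLLICULAR_ADENOMA"
    ADENOMATOID_NODULE = "ADENOMATOID_NODULE"


MALIGNANT_HISTOLOGIES = frozenset(
    {
        Histology.PTC,
        Histology.MICRO_PTC,
        Histology.PTCFV,
        Histology.NIFTP,
        Histology.HTC,
        Histology.PDTC,
        Histology.MTC,
    }
)


def truth_of(histology: Histology) -> Truth:
    """Truth label is a deterministic function of histology."""
    return Truth.MALIGNANT if histology in MALIGNANT_HISTOLOGIES else Truth.BENIGN


@dataclass(frozen=True)
class AlterationEvent:
    """One categorical outcome of a histology's alteration spectrum: a set of
    co-occurring alterations drawn together with the given probability."""

    probability: float
    alterations: tuple[GenomicAlteration, ...]

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError("bad-probability", f"event probability {self.probability}")


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    ``histology_mix`` is the unconditional distribution over histologies; a
    nodule first draws malignancy ~ Bernoulli(``malignancy_prevalence``) and
    then a histology from the mix renormalized within the matching truth
    stratum. ``us_pattern_dist`` maps each truth label to a distribution over
    ATA patterns. ``alteration_spectrum`` maps each histology to its list of
    categorical events; probabilities may sum to less than 1, the remainder
    being panel-negative.
    """

    n_patients: int
    malignancy_prevalence: float
    histology_mix: dict[Histology, float]
    alteration_spectrum: dict[Histology, list[AlterationEvent]]
    us_pattern_dist: dict[Truth, dict[AtaPattern, float]]
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValidationError("bad-n", "n_patients must be > 0")
        if not 0.0 <= self.malignancy_prevalence <= 1.0:
            raise ValidationError("bad-prevalence", "malignancy_prevalence must be in [0, 1]")
        if abs(sum(self.histology_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("bad-mix", "histology_mix must sum to 1")
        if any(p < 0 for p in self.histology_mix.values()):
            raise ValidationError("bad-mix", "histology_mix has negative mass")
        for truth, dist in self.us_pattern_dist.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9 or any(p < 0 for p in dist.values()):
                raise ValidationError("bad-pattern-dist", f"pattern distribution for {truth}")
        for hist, events in self.alteration_spectrum.items():
            total = sum(e.probability for e in events)
            if total > 1.0 + 1e-9:
                raise ValidationError(
                    "bad-spectrum", f"event probabilities for {hist} sum to {total} > 1"
                )
        for truth in (Truth.MALIGNANT, Truth.BENIGN):
            if self._stratum_mass(truth) <= 0:
                raise ValidationError("bad-mix", f"histology_mix has no {truth.value} mass")

    def _stratum_mass(self, truth: Truth) -> float:
        return sum(p for h, p in self.histology_mix.items() if truth_of(h) is truth)

    def histology_given_truth(self, truth: Truth) -> dict[Histology, float]:
        """Histology distribution conditional on the truth stratum."""
        mass = self._stratum_mass(truth)
        return {
            h: p / mass
            for h, p in self.histology_mix.items()
            if truth_of(h) is truth and p > 0
        }


@dataclass(frozen=True)
class SyntheticNodule:
    nodule_id: str
    histology: Histology
    truth: Truth
    pattern: AtaPattern
    alterations: tuple[GenomicAlteration, ...]

    @property
    def x_us(self) -> float:
        return xus_from_pattern(self.pattern)


def _pick(u: float, items: Sequence, probs: Sequence[float]):
    """Categorical draw from one uniform; returns None on the remainder mass."""
    acc = 0.0
    for item, p in zip(items, probs):
        acc += p
        if u < acc:
            return item
    return None


def generate_cohort(config: CohortConfig) -> list[SyntheticNodule]:
    """Generate ``config.n_patients`` nodules, reproducibly from ``config.seed``.

    Per nodule, draws are consumed in the fixed order: malignancy flag,
    histology, ultrasound pattern, alteration event.
    """
    rng = np.random.default_rng(config.seed)
    nodules: list[SyntheticNodule] = []
    for i in range(config.n_patients):
        u_mal, u_hist, u_pat, u_alt = rng.random(4)
        truth = Truth.MALIGNANT if u_mal < config.malignancy_prevalence else Truth.BENIGN
        hist_dist = config.histology_given_truth(truth)
        hists, hps = zip(*sorted(hist_dist.items(), key=lambda kv: kv[0].value))
        histology = _pick(u_hist, hists, hps)
        if histology is None:  # float round-off on the last bin
            histology = hists[-1]
        pat_dist = config.us_pattern_dist[truth]
        pats, pps = zip(*sorted(pat_dist.items(), key=lambda kv: kv[0].value))
        pattern = _pick(u_pat, pats, pps)
        if pattern is None:
            pattern = pats[-1]
        events = config.alteration_spectrum.get(histology, [])
        event = _pick(u_alt, events, [e.probability for e in events])
        alterations = event.alterations if event is not None else ()
        nodules.append(
            SyntheticNodule(
                nodule_id=f"N{i + 1:04d}",
                histology=histology,
                truth=truth,
                pattern=pattern,
                alterations=alterations,
            )
        )
    return nodules


# ---------------------------------------------------------------------------
# Default study-like configuration.
# ---------------------------------------------------------------------------

def _alt(gene: str, detail: str, cls: str) -> GenomicAlteration:
    from .genomics import AlterationClass

    return GenomicAlteration(gene=gene, alteration_class=AlterationClass(cls), detail=detail)


_BRAF = _alt("BRAF", "p.Val600Glu", "SNV")
_TERT = _alt("TERT", "c.1-124C>T", "SNV")
_NRAS_Q61R = _alt("NRAS", "p.Gln61Arg", "SNV")
_NRAS_Q61K = _alt("NRAS", "p.Gln61Lys", "SNV")
_KRAS_Q61R = _alt("KRAS", "p.Gln61Arg", "SNV")
_HRAS_Q61R = _alt("HRAS", "p.Gln61Arg", "SNV")
_RET_C634R = _alt("RET", "p.Cys634Arg", "SNV")
_RET_M918T = _alt("RET", "p.Met918Thr", "SNV")
_RET_DEL = _alt("RET", "deletion", "CNV")
_PAX8_PPARG = _alt("PAX8", "PAX8-PPARG", "GENE_FUSION")
_SLX4 = _alt("SLX4", "p.Glu1517Ter", "SNV")
_ATM = _alt("ATM", "p.Asp2708Asn", "SNV")
_GNAS = _alt("GNAS", "p.Arg201Cys", "SNV")
_ESR1 = _alt("ESR1", "p.Tyr537Ser", "SNV")
_TET2 = _alt("TET2", "p.Gln742Ter", "SNV")
_CCND1_AMP = _alt("CCND1", "amplification", "CNV")


def _ev(p: Fraction | float, *alterations: GenomicAlteration) -> AlterationEvent:
    return AlterationEvent(probability=float(p), alterations=tuple(alterations))


_BENIGN_SPECTRUM = [
    _ev(Fraction(2, 19), _HRAS_Q61R),
    _ev(Fraction(1, 19), _NRAS_Q61K),
    _ev(Fraction(1, 19), _NRAS_Q61K, _ATM),
    _ev(Fraction(1, 19), _GNAS),
    _ev(Fraction(1, 19), _ESR1),
    _ev(Fraction(1, 19), _TET2),
]  # panel-positive mass 7/19


def default_study_config(n_patients: int = 47, seed: int = 0) -> CohortConfig:
    """Study-like cohort configuration.

    Calibrated so that, in expectation, the generated cohort reproduces the
    pilot cohort's printed marginals: histology mix 28/47 carcinoma split
    11 PTC / 4 micro-PTC / 6 PTCFV / 1 NIFTP / 2 HTC / 1 PDTC / 3 MTC and
    19/47 benign (6 follicular adenoma, 13 adenomatoid nodule); panel
    positivity 22/28 among carcinomas and 7/19 among benign nodules; 12/28
    BRAF V600E carriers and 4/28 RAS carriers among carcinomas; ultrasound
    patterns enriched for high suspicion in malignancy (9/26 high | malignant
    vs 2/21 | benign, the conditionals implied by the study's 2x2 tables).
    """
    mix = {
        Histology.PTC: Fraction(11, 47),
        Histology.MICRO_PTC: Fraction(4, 47),
        Histology.PTCFV: Fraction(6, 47),
        Histology.NIFTP: Fraction(1, 47),
        Histology.HTC: Fraction(2, 47),
        Histology.PDTC: Fraction(1, 47),
        Histology.MTC: Fraction(3, 47),
        Histology.FOLLICULAR_ADENOMA: Fraction(6, 47),
        Histology.ADENOMATOID_NODULE: Fraction(13, 47),
    }
    spectrum = {
        Histology.PTC: [
            _ev(Fraction(7, 11), _BRAF),
            _ev(Fraction(1, 11), _BRAF, _TERT),
            _ev(Fraction(1, 11), _CCND1_AMP),
        ],
        Histology.MICRO_PTC: [_ev(Fraction(1, 2), _BRAF)],
        Histology.PTCFV: [
            _ev(Fraction(1, 3), _BRAF),
            _ev(Fraction(1, 6), _NRAS_Q61R),
            _ev(Fraction(1, 6), _KRAS_Q61R),
        ],
        Histology.NIFTP: [_ev(1.0, _PAX8_PPARG)],
        Histology.HTC: [
            _ev(Fraction(1, 2), _NRAS_Q61R, _SLX4, _ATM),
            _ev(Fraction(1, 2), _SLX4, _ATM),
        ],
        Histology.PDTC: [_ev(1.0, _HRAS_Q61R)],
        Histology.MTC: [
            _ev(Fraction(1, 3), _RET_C634R),
            _ev(Fraction(1, 3), _RET_M918T),
            _ev(Fraction(1, 3), _RET_DEL),
        ],
        Histology.FOLLICULAR_ADENOMA: list(_BENIGN_SPECTRUM),
        Histology.ADENOMATOID_NODULE: list(_BENIGN_SPECTRUM),
    }
    pattern_dist = {
        Truth.MALIGNANT: {
            AtaPattern.HIGH: Fraction(9, 26),
            AtaPattern.INTERMEDIATE: Fraction(12, 26),
            AtaPattern.LOW: Fraction(5, 26),
        },
        Truth.BENIGN: {
            AtaPattern.HIGH: Fraction(2, 21),
            AtaPattern.INTERMEDIATE: Fraction(8, 21),
            AtaPattern.LOW: Fraction(11, 21),
        },
    }
    return CohortConfig(
        n_patients=n_patients,
        malignancy_prevalence=float(Fraction(28, 47)),
        histology_mix={h: float(p) for h, p in mix.items()},
        alteration_spectrum=spectrum,
        us_pattern_dist={
            t: {p: float(v) for p, v in d.items()} for t, d in pattern_dist.items()
        },
        seed=seed,
    )


def scale_malignant_event_probabilities(config: CohortConfig, factor: float) -> CohortConfig:
    """Return a config with every malignant histology's event probabilities
    multiplied by ``factor`` (total mass capped at 1). Used for monotonicity
    checks: more alterations can only increase genomic-score sensitivity."""
    new_spectrum: dict[Histology, list[AlterationEvent]] = {}
    for hist, events in config.alteration_spectrum.items():
        if truth_of(hist) is not Truth.MALIGNANT or not events:
            new_spectrum[hist] = list(events)
            continue
        total = sum(e.probability for e in events)
        eff = min(factor, 1.0 / total) if total > 0 else factor
        new_spectrum[hist] = [replace(e, probability=e.probability * eff) for e in events]
    return replace(config, alteration_spectrum=new_spectrum)


# ---------------------------------------------------------------------------
# Config-implied (analytic) operating characteristics.
# ---------------------------------------------------------------------------

def _event_space(events: Sequence[AlterationEvent]):
    """Outcomes of a histology's categorical spectrum incl. panel-negative."""
    outcomes = [(e.probability, e.alterations) for e in events]
    rest = 1.0 - sum(e.probability for e in events)
    if rest > 1e-12:
        outcomes.append((rest, ()))
    return outcomes


def expected_positivity(config: CohortConfig) -> dict[Truth, float]:
    """Probability of carrying at least one alteration, by truth stratum."""
    out = {}
    for truth in (Truth.MALIGNANT, Truth.BENIGN):
        total = 0.0
        for hist, ph in config.histology_given_truth(truth).items():
            pos = sum(
                p for p, alts in _event_space(config.alteration_spectrum.get(hist, []))
                if len(alts) > 0
            )
            total += ph * pos
        out[truth] = total
    return out


def expected_alteration_rate(config: CohortConfig, gene: str, truth: Truth) -> float:
    """Probability that a nodule of the given stratum carries >= 1 alteration
    of ``gene`` (marginal carrier rate, e.g. BRAF among malignant)."""
    total = 0.0
    for hist, ph in config.histology_given_truth(truth).items():
        carrier = sum(
            p for p, alts in _event_space(config.alteration_spectrum.get(hist, []))
            if any(a.gene.upper() == gene.upper() for a in alts)
        )
        total += ph * carrier
    return total


def expected_performance(
    config: CohortConfig,
    weights: Optional[WeightTable] = None,
    xus_cutoff: float = XUS_CUTOFF,
    xgc_cutoff: float = XGC_CUTOFF,
    trs_cutoff: float = TRS_CUTOFF,
) -> dict[str, tuple[float, float]]:
    """Exact (sensitivity, specificity) implied by the config for each score.

    Enumerates the joint distribution of (histology, alteration event,
    ultrasound pattern) within each truth stratum — the spectra are finite
    categoricals, so no simulation is involved. Used as the ground truth for
    parameter-recovery checks of the generator.
    """
    weights = weights or default_weight_table()
    out: dict[str, dict[Truth, float]] = {"x_us": {}, "x_gc": {}, "trs": {}}
    for truth in (Truth.MALIGNANT, Truth.BENIGN):
        pat_dist = config.us_pattern_dist[truth]
        p_us_pos = sum(
            p for pat, p in pat_dist.items() if ge(xus_from_pattern(pat), xus_cutoff)
        )
        p_gc_pos = 0.0
        p_trs_pos = 0.0
        for hist, ph in config.histology_given_truth(truth).items():
            for pe, alts in _event_space(config.alteration_spectrum.get(hist, [])):
                xgc = compute_xgc(alts, weights).x_gc
                if ge(xgc, xgc_cutoff):
                    p_gc_pos += ph * pe
                p_pat = sum(
                    pp for pat, pp in pat_dist.items()
                    if ge(xus_from_pattern(pat) + xgc, trs_cutoff)
                )
                p_trs_pos += ph * pe * p_pat
        out["x_us"][truth] = p_us_pos
        out["x_gc"][truth] = p_gc_pos
        out["trs"][truth] = p_trs_pos
    return {
        score: (rates[Truth.MALIGNANT], 1.0 - rates[Truth.BENIGN])
        for score, rates in out.items()
    }
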