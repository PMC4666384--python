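"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here without downloads:
random PWMs with a controlled information content, 61-mer SNV scenarios in
which a known motif's site is destroyed or created (plus neutral controls),
and ChIP-peak-like datasets for chemical-potential estimation. The
generators are deterministic in the supplied ``numpy.random.Generator``.

The planted-case design mirrors a verified-regulatory-variant benchmark:
one informative "true" motif whose consensus site spans the variant
position, buried among independently drawn decoy motifs, with i.i.d.
flanking sequence. Decoys are unconstrained and may resemble the true
motif by chance; that is reported by the benchmark, not prevented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import psi

from .motifs import BASES, EnergyMatrix, Pwm, batch_window_energies, binding_probability, encode_sequence
from .potentials import PeakDataset

__all__ = [
    "SCENARIOS",
    "PlantedCase",
    "random_pwm",
    "make_planted_case",
    "simulate_chip_peaks",
    "write_fasta",
]

log = logging.getLogger(__name__)

SCENARIOS = ("destroy", "create", "neutral")


@dataclass(frozen=True)
class PlantedCase:
    """One synthetic SNV scenario with its true motif and decoy collection.

    ``expected_direction`` names the ranking list ("positive" or "negative")
    that should contain the true TF: destroying a site leaves binding higher
    on the reference (positive score), creating one leaves it higher on the
    mutant (negative score). Neutral cases have no expected direction.
    """

    true_motif: Pwm
    decoys: tuple
    ref_seq: str
    mut_seq: str
    scenario: str
    expected_direction: Optional[str]
    snp_pos: int  # 0-based position of the variant within the window
    site_start: Optional[int]  # 0-based start of the planted site, None for neutral

    def all_pwms(self) -> list:
        return [self.true_motif, *self.decoys]


def _dirichlet_concentration(ic_target: float) -> float:
    """Symmetric Dirichlet concentration whose expected column IC matches the target.

    For Dirichlet(a, a, a, a) the expected entropy is psi(4a + 1) - psi(a + 1)
    nats, hence expected IC = 2 - that / ln 2 bits, strictly decreasing in a.
    """
    def gap(log_a: float) -> float:
        a = np.exp(log_a)
        ic = 2.0 - (psi(4 * a + 1) - psi(a + 1)) / np.log(2)
        return ic - ic_target

    lo, hi = np.log(1e-4), np.log(1e4)
    if gap(lo) <= 0:  # target at or above what the sparsest Dirichlet reaches
        return float(np.exp(lo))
    if gap(hi) >= 0:
        return float(np.exp(hi))
    return float(np.exp(brentq(gap, lo, hi, xtol=1e-10)))


def random_pwm(
    rng: np.random.Generator,
    m: int,
    ic_target: float,
    id: str = "random",
    tf_name: Optional[str] = None,
    ic_tol: float = 0.2,
    max_tries: int = 100,
) -> Pwm:
    """Random PWM whose mean per-column information content hits ``ic_target``.

    Columns are drawn from a symmetric Dirichlet whose concentration is
    solved so the expected column IC equals the target; draws are rejected
    until the realised mean IC is within ``ic_tol`` bits.
    """
    if not 4 <= m <= 20:
        raise ValueError(f"motif width must be in [4, 20], got {m}")
    if not 0 < ic_target <= 2:
        raise ValueError(f"ic_target must be in (0, 2], got {ic_target}")
    conc = _dirichlet_concentration(ic_target)
    best: Optional[Pwm] = None
    best_gap = np.inf
    for _ in range(max_tries):
        cols = rng.dirichlet([conc] * 4, size=m).T
        pwm = Pwm(id=id, tf_name=tf_name if tf_name is not None else id, probs=cols)
        gap = abs(float(pwm.information_content().mean()) - ic_target)
        if gap < best_gap:
            best, best_gap = pwm, gap
        if gap <= ic_tol:
            return pwm
    log.warning("random_pwm: mean IC missed target %.2f by %.2f bits", ic_target, best_gap)
    return best


def _random_bases(rng: np.random.Generator, n: int, gc: float = 0.5) -> list:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return [BASES[i] for i in rng.choice(4, size=n, p=probs)]


def make_planted_case(
    rng: np.random.Generator,
    scenario: str,
    n_decoys: int,
    flank: int = 30,
    gc: float = 0.5,
    true_ic: float = 1.8,
    true_width: tuple = (8, 12),
    decoy_ic: tuple = (0.8, 1.6),
    decoy_width: tuple = (6, 14),
) -> PlantedCase:
    """Build one SNV scenario with a planted true motif and random decoys.

    The true motif (mean IC >= 1.5 bits/column) has its consensus site
    placed so that its most informative column sits at the variant position
    (the window centre). ``destroy``: the reference carries the consensus
    and the variant substitutes the least favourable base there;
    ``create``: the reverse; ``neutral``: no site is planted and the
    variant swaps two random bases at the centre.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    if n_decoys < 1:
        raise ValueError(f"n_decoys must be >= 1, got {n_decoys}")

    for _ in range(50):
        m = int(rng.integers(true_width[0], true_width[1] + 1))
        true = random_pwm(rng, m, true_ic, id="true_motif", tf_name="TRUE_TF")
        if float(true.information_content().mean()) >= 1.5:
            break
    decoys = tuple(
        random_pwm(
            rng,
            int(rng.integers(decoy_width[0], decoy_width[1] + 1)),
            float(rng.uniform(decoy_ic[0], decoy_ic[1])),
            id=f"decoy_{i:03d}",
            tf_name=f"DECOY{i:03d}",
        )
        for i in range(n_decoys)
    )

    L = 2 * flank + 1
    seq = _random_bases(rng, L, gc)
    snp_pos = flank
    if scenario == "neutral":
        ref_base = seq[snp_pos]
        alt_base = BASES[(BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
        ref = seq.copy()
        mut = seq.copy()
        mut[snp_pos] = alt_base
        site_start = None
    else:
        ic = true.information_content()
        j_star = int(np.argmax(ic))  # most informative column carries the SNP
        site_start = flank - j_star
        consensus = true.consensus()
        for j, base in enumerate(consensus):
            seq[site_start + j] = base
        worst = BASES[int(np.argmin(true.probs[:, j_star]))]
        ref = seq.copy()
        mut = seq.copy()
        if scenario == "destroy":
            mut[snp_pos] = worst
        else:  # create: the site only exists on the mutated allele
            ref[snp_pos] = worst
    return PlantedCase(
        true_motif=true,
        decoys=decoys,
        ref_seq="".join(ref),
        mut_seq="".join(mut),
        scenario=scenario,
        expected_direction={"destroy": "positive", "create": "negative", "neutral": None}[scenario],
        snp_pos=snp_pos,
        site_start=site_start,
    )


def simulate_chip_peaks(
    rng: np.random.Generator,
    energy: EnergyMatrix,
    mu_true: float,
    n_peaks: int = 200,
    noise_sd_fraction: float = 0.1,
    length: int = 200,
    scale: float = 100.0,
    gc: float = 0.5,
) -> PeakDataset:
    """Simulate ChIP peak sequences with occupancy-proportional signals.

    Each peak is a ``length``-mer of i.i.d. background with one site planted
    at a random offset, its bases drawn per column from the Boltzmann
    weights exp(-E[b, j]) so that site strengths spread around the consensus.
    The clean signal is ``scale`` times the Fermi-Dirac occupancy at
    ``mu_true``; Gaussian noise with standard deviation
    ``noise_sd_fraction * mean(clean)`` is added and signals are floored
    at 0.
    """
    if n_peaks < 10:
        raise ValueError(f"n_peaks must be >= 10, got {n_peaks}")
    m = energy.m
    if m >= length:
        raise ValueError(f"motif width {m} must be smaller than peak length {length}")
    weights = np.exp(-energy.E)
    weights /= weights.sum(axis=0)
    seqs = []
    for _ in range(n_peaks):
        bases = _random_bases(rng, length, gc)
        offset = int(rng.integers(0, length - m + 1))
        for j in range(m):
            bases[offset + j] = BASES[int(rng.choice(4, p=weights[:, j]))]
        seqs.append("".join(bases))
    codes = np.array([encode_sequence(s) for s in seqs])
    ew = batch_window_energies(energy, codes)
    clean = scale * binding_probability(ew, mu_true).sum(axis=1)
    sd = noise_sd_fraction * float(clean.mean())
    signals = clean if sd == 0 else np.maximum(clean + rng.normal(0.0, sd, n_peaks), 0.0)
    return PeakDataset(sequences=tuple(seqs), signals=signals)


def write_fasta(path, records) -> None:
    """Write (name, sequence) pairs as FASTA."""
    with open(path, "w") as out:
        for name, seq in records:
            out.write(f">{name}\n{seq}\n")
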