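"""Ground-truth screen simulator.

Generates self-targeting screen data with the statistical structure seen in
tiled ABE screens: a positional editing window, trinucleotide-context and
PAM-class activity, delivery-dose saturation of site-level editing rates,
replicate-level noise and multinomial read sampling.  Every generated dataset
comes with its exact ground truth, so the simulator doubles as the oracle for
the quantification and prediction modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .outcomes import (
    Outcome,
    OutcomeDistribution,
    apply_edits,
    editable_positions,
    per_position_efficiency,
    total_efficiency,
)
from .screen import ScreenDataset
from .seqcore import TargetSite, design_tiling_sgrnas

NUCS = "ACGT"
ALL_TRINUCS = [a + b + c for a in NUCS for b in NUCS for c in NUCS]
ALL_MOTIFS = [a + "A" + b for a in NUCS for b in NUCS]

#: PAM classes scanned by the tiling designer (SpRY-compatible set)
DESIGN_PAM_CLASSES = ("NGN", "NAN", "NCW", "NTR")


def _gaussian_window(center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    p = np.arange(1, 21, dtype=float)
    return np.exp(-((p - center) ** 2) / (2.0 * sigma ** 2))


def _default_context_multipliers() -> dict[str, float]:
    """Mild 5'N-A-3'N preferences with an elevated T-A-C motif."""
    base = {
        "A": 0.9, "C": 1.0, "G": 0.8, "T": 1.2,   # 5' neighbour effect
    }
    after = {
        "A": 0.9, "C": 1.25, "G": 1.0, "T": 0.85,  # 3' neighbour effect
    }
    return {m: base[m[0]] * after[m[2]] for m in ALL_MOTIFS}


def _spry_pam_activity() -> dict[str, float]:
    """SpRY-like PAM activity: NRN ≫ NYN, with NGN slightly above NAN."""
    second = {"G": 1.0, "A": 0.85, "C": 0.22, "T": 0.18}
    return {t: second[t[1]] for t in ALL_TRINUCS}


@dataclass
class EditorProfile:
    """Ground-truth per-editor simulator parameters."""

    name: str = "abe8e-like"
    window_center: float = 6.0
    window_width: float = 11.0           # positions at half maximum
    base_rate: float = 0.5               # per-A latent propensity at window peak
    position_activity: np.ndarray = None
    context_multipliers: dict = field(default_factory=_default_context_multipliers)
    pam_activity: dict = field(default_factory=_spry_pam_activity)
    interaction: float = 0.0             # optional adjacent-coedit boost

    def __post_init__(self):
        if self.position_activity is None:
            self.position_activity = _gaussian_window(self.window_center, self.window_width)
        self.position_activity = np.asarray(self.position_activity, dtype=float)
        if self.position_activity.shape != (20,):
            raise ValueError("position_activity must have length 20")
        if np.any(self.position_activity < 0) or np.any(self.position_activity > 1):
            raise ValueError("position activities must lie in [0, 1]")
        if any(v <= 0 for v in self.context_multipliers.values()):
            raise ValueError("context multipliers must be positive")
        missing = set(ALL_TRINUCS) - set(self.pam_activity)
        if missing:
            raise ValueError(f"pam_activity missing {len(missing)} trinucleotides")
        if any(not 0 <= v <= 1 for v in self.pam_activity.values()):
            raise ValueError("pam activities must lie in [0, 1]")

    @classmethod
    def abe8e_like(cls) -> "EditorProfile":
        return cls(name="abe8e-like", window_width=11.0, base_rate=0.5)

    @classmethod
    def abemax_like(cls) -> "EditorProfile":
        return cls(name="abemax-like", window_width=7.0, base_rate=0.3)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["position_activity"] = [float(x) for x in self.position_activity]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EditorProfile":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["position_activity"] = np.array(d["position_activity"], dtype=float)
        return cls(**d)


@dataclass
class DoseModel:
    """Delivery-dose response: a scaled logistic through the origin.

    Maps a latent editing propensity x ≥ 0 to the observed editing
    probability ``ceiling * (2 / (1 + exp(-dose*x)) - 1)``: strictly
    increasing in x and in dose, zero at zero and bounded by ``ceiling``.
    High dose compresses site-to-site differences against the ceiling
    (plasmid-like saturation); low dose stays near-linear (mRNA/in vivo-like).
    """

    dose: float = 1.0
    ceiling: float = 0.45

    def __post_init__(self):
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if not 0 < self.ceiling <= 1:
            raise ValueError("ceiling must lie in (0, 1]")

    def saturation(self, x):
        x = np.asarray(x, dtype=float)
        return self.ceiling * (2.0 / (1.0 + np.exp(-self.dose * x)) - 1.0)

    @classmethod
    def plasmid_like(cls) -> "DoseModel":
        return cls(dose=8.0, ceiling=0.45)

    @classmethod
    def mrna_like(cls, dose: float = 2.0) -> "DoseModel":
        return cls(dose=dose, ceiling=0.45)


def motif_at(site: TargetSite, pos: int) -> str:
    """5'N-A-3'N context of protospacer position ``pos`` (1-based)."""
    left = site.protospacer[pos - 2] if pos >= 2 else (site.flank5[-1] if site.flank5 else "N")
    right = site.protospacer[pos] if pos <= 19 else site.pam_context[0]
    return left + site.protospacer[pos - 1] + right


def latent_per_a(site: TargetSite, profile: EditorProfile) -> dict[int, float]:
    """Dose-free latent editing propensity for each editable adenine."""
    out = {}
    for p in editable_positions(site.protospacer):
        motif = motif_at(site, p)
        x = (profile.base_rate
             * profile.position_activity[p - 1]
             * profile.context_multipliers.get(motif, 1.0)
             * profile.pam_activity[site.pam3])
        out[p] = min(max(x, 0.0), 1.0)
    return out


def per_a_probabilities(site: TargetSite, profile: EditorProfile, dose: DoseModel,
                        logit_shift: float = 0.0) -> dict[int, float]:
    """Observed per-adenine editing probability for each editable position.

    The dose response acts on the *site-level* latent total efficiency
    (editor expression saturates what a site can reach, piling efficiencies
    against the ceiling at high dose, as plasmid delivery does); per-adenine
    rates are then rescaled by a common factor so that independent per-A
    editing reproduces that total.  For a single-A site this reduces to
    applying the saturation to the adenine itself.  ``logit_shift`` adds
    replicate-level noise to the site total on the log-odds scale.
    """
    x = latent_per_a(site, profile)
    if not x:
        return {}
    vals = np.array(list(x.values()))
    latent_total = 1.0 - np.prod(1.0 - vals)
    target = float(dose.saturation(latent_total))
    if logit_shift != 0.0 and 0.0 < target < 1.0:
        target = 1.0 / (1.0 + math.exp(-(math.log(target / (1 - target)) + logit_shift)))
    if target <= 0.0 or latent_total <= 0.0:
        return {p: 0.0 for p in x}
    vmax = vals.max()
    lo, hi = 0.0, 1.0 / vmax
    for _ in range(60):                      # bisection: total is monotone in c
        c = 0.5 * (lo + hi)
        if 1.0 - np.prod(1.0 - c * vals) < target:
            lo = c
        else:
            hi = c
    c = 0.5 * (lo + hi)
    return {p: min(c * v, 1.0) for p, v in x.items()}


def true_site_distribution(site: TargetSite, profile: EditorProfile,
                           dose: DoseModel, logit_shift: float = 0.0) -> OutcomeDistribution:
    """Exact outcome distribution under independent per-adenine editing.

    With ``profile.interaction`` ≠ 0, outcomes gain a multiplicative
    ``(1+interaction)`` factor per adjacent co-edited pair and the distribution
    is renormalized, breaking per-A independence.
    """
    pa = per_a_probabilities(site, profile, dose, logit_shift)
    pos = sorted(pa)
    k = len(pos)
    outcomes, weights = [], []
    for m in range(2 ** k):
        chosen = tuple(pos[j] for j in range(k) if m >> j & 1)
        w = 1.0
        for p in pos:
            w *= pa[p] if p in chosen else 1.0 - pa[p]
        if profile.interaction:
            adj = sum(1 for a, b in zip(chosen, chosen[1:]) if b - a == 1)
            w *= (1.0 + profile.interaction) ** adj
        outcomes.append(apply_edits(site.protospacer, chosen))
        weights.append(w)
    probs = np.array(weights)
    probs /= probs.sum()
    return OutcomeDistribution(site.site_id, outcomes, probs)


def sample_reads(dist: OutcomeDistribution, depth: int, seed_or_rng) -> dict[Outcome, int]:
    """Multinomial read sampling at the given depth (empty table at depth 0)."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    if depth == 0:
        return {}
    draws = rng.multinomial(depth, dist.probs / dist.probs.sum())
    return {o: int(n) for o, n in zip(dist.outcomes, draws) if n > 0}


def random_locus(rng: np.random.Generator, length: int = 80,
                 variant_offset: int = 40) -> str:
    seq = rng.choice(list(NUCS), size=length)
    seq[variant_offset] = "A"
    return "".join(seq)


def generate_screen(
    n_sites: int,
    profile: EditorProfile | None = None,
    dose: DoseModel | None = None,
    depth: int = 5000,
    replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    pam_classes=DESIGN_PAM_CLASSES,
    coding_fraction: float = 0.8,
    sites: list[TargetSite] | None = None,
) -> tuple[ScreenDataset, pd.DataFrame]:
    """Simulate a tiled self-targeting screen with paired ground truth.

    Random loci are pushed through the tiling designer, so each "gene" is one
    pathogenic-variant locus carrying 2-6 sgRNAs that share sequence context
    (the leakage structure that motivates gene-level splitting).  Per replicate,
    site efficiencies receive a shared log-odds shift with sd ``noise_sd``
    before multinomial sampling at ``depth`` reads.

    Returns the dataset and a truth table with the exact (noise-free) total
    and per-position efficiencies of every site.
    """
    profile = profile or EditorProfile.abe8e_like()
    dose = dose or DoseModel.mrna_like()
    rng = np.random.default_rng(seed)
    if sites is None:
        sites = []
        gene = 0
        attempts = 0
        while len(sites) < n_sites:
            attempts += 1
            if attempts > 50 * n_sites:
                raise RuntimeError("designer yield too low for requested n_sites")
            locus = random_locus(rng)
            frame = int(rng.integers(3)) if rng.random() < coding_fraction else "noncoding"
            cand = design_tiling_sgrnas(
                locus, 40, pam_classes,
                site_id_prefix=f"g{gene:05d}", gene_id=f"g{gene:05d}",
                variant_frame=frame,
            )
            if len(cand) < 2:      # keep ≥2 sites/gene so gene splits bite
                continue
            sites.extend(cand)
            gene += 1
        sites = sites[:n_sites]
    else:
        sites = list(sites)

    ds = ScreenDataset(sites=sites, metadata={
        "editor": profile.name, "dose": dose.dose, "ceiling": dose.ceiling,
        "depth": depth, "replicates": replicates, "noise_sd": noise_sd, "seed": seed,
    })
    truth_rows = []
    rep_ids = [f"rep{i+1}" for i in range(replicates)]
    for site in sites:
        true_dist = true_site_distribution(site, profile, dose)
        pp = per_position_efficiency(true_dist)
        row = {
            "site_id": site.site_id, "gene_id": site.gene_id,
            "pam": site.pam3, "target_pos": site.target_pos,
            "true_eff": total_efficiency(true_dist),
        }
        row.update({f"pos{p}": pp[p - 1] for p in range(1, 21)})
        truth_rows.append(row)
        for rep in rep_ids:
            shift = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rep_dist = (true_dist if shift == 0.0
                        else true_site_distribution(site, profile, dose, shift))
            table = sample_reads(rep_dist, depth, rng)
            if table:
                ds.counts.setdefault(site.site_id, {})[rep] = table
    return ds, pd.DataFrame(truth_rows)


def synthesize_read(site: TargetSite, outcome: Outcome, scaffold: str,
                    flank_len: int = 30) -> str:
    """Full oligo read (spacer+scaffold+cassette) with the outcome's edits applied."""
    spacer = site.protospacer if site.protospacer[0] == "G" else "G" + site.protospacer[1:]
    used5 = site.flank5[-flank_len:] if flank_len else ""
    used3 = site.flank3[:flank_len]
    return spacer + scaffold + used5 + outcome.sequence + site.pam3 + used3


def reads_from_counts(ds: ScreenDataset, scaffold: str, flank_len: int = 30):
    """Yield (replicate, read) pairs reconstructing raw reads from count tables."""
    for site in ds.sites:
        for rep, table in ds.counts.get(site.site_id, {}).items():
            for outcome, n in table.items():
                read = synthesize_read(site, outcome, scaffold, flank_len)
                for _ in range(n):
                    yield rep, read
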