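"""Screen quantification: read counting, filtering, replicate agreement, PAM
matrices, editing windows, context motifs and bystander classification.

The central container is :class:`ScreenDataset`: a library of target sites with
per-site, per-replicate tables of outcome read counts.  Reads that carry indels
or too many non-A→G mismatches inside the protospacer are kept in a separate
"other" bucket and excluded from outcome frequencies, so efficiencies are
always conditional on clean A→G outcomes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .outcomes import (
    Outcome,
    OutcomeDistribution,
    apply_edits,
    per_position_efficiency,
    total_efficiency,
)
from .seqcore import TargetSite, resolve_pam_classes

logger = logging.getLogger(__name__)

NUCS = "ACGT"
DINUCS = [a + b for a in NUCS for b in NUCS]


@dataclass
class ScreenDataset:
    """A screening dataset: sites plus per-replicate outcome read counts."""

    sites: list
    counts: dict = field(default_factory=dict)   # site_id -> rep_id -> {Outcome: int}
    other: dict = field(default_factory=dict)    # site_id -> rep_id -> int
    unassigned: dict = field(default_factory=dict)  # rep_id -> int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site_id in dataset")
        self._by_id = {s.site_id: s for s in self.sites}

    def site(self, site_id: str) -> TargetSite:
        return self._by_id[site_id]

    @property
    def replicates(self) -> list[str]:
        reps = set()
        for per_rep in self.counts.values():
            reps.update(per_rep)
        return sorted(reps)

    def assigned_reads(self, site_id: str, rep: str) -> int:
        return sum(self.counts.get(site_id, {}).get(rep, {}).values())

    def distribution(self, site_id: str, rep: str | None = None) -> OutcomeDistribution | None:
        """Observed outcome distribution; pooled over replicates when rep is None."""
        per_rep = self.counts.get(site_id, {})
        pooled: Counter = Counter()
        for r, table in per_rep.items():
            if rep is None or r == rep:
                pooled.update(table)
        total = sum(pooled.values())
        if total == 0:
            return None
        site = self.site(site_id)
        wt = apply_edits(site.protospacer, ())
        if wt not in pooled:
            pooled[wt] = 0
        outs = sorted(pooled, key=lambda o: o.positions)
        probs = np.array([pooled[o] for o in outs], dtype=float) / total
        return OutcomeDistribution(site_id, outs, probs)

    def total_efficiency(self, site_id: str, rep: str | None = None) -> float | None:
        dist = self.distribution(site_id, rep)
        return None if dist is None else total_efficiency(dist)

    def efficiency_series(self, rep: str | None = None) -> pd.Series:
        vals = {}
        for s in self.sites:
            e = self.total_efficiency(s.site_id, rep)
            if e is not None:
                vals[s.site_id] = e
        return pd.Series(vals, name="total_eff")

    def subset(self, site_ids) -> "ScreenDataset":
        keep = set(site_ids)
        return ScreenDataset(
            sites=[s for s in self.sites if s.site_id in keep],
            counts={k: v for k, v in self.counts.items() if k in keep},
            other={k: v for k, v in self.other.items() if k in keep},
            unassigned=dict(self.unassigned),
            metadata=dict(self.metadata),
        )


def count_outcomes(reads, library, scaffold: str, mismatch_budget: int = 1,
                   flank_len: int = 30, metadata: dict | None = None) -> ScreenDataset:
    """Assign reads to library sites by exact spacer match and tabulate outcomes.

    ``reads`` is either an iterable of sequences/SeqRecords (one replicate) or a
    mapping replicate-id -> iterable.  Each read must span spacer + scaffold +
    target cassette.  Within the protospacer, A→G substitutions define the
    outcome; an indel (cassette length change) or more than ``mismatch_budget``
    non-A→G mismatches sends the read to the "other" bucket.  Read totals are
    conserved: assigned + other + unassigned = input.
    """
    spacer_map = {}
    for site in library:
        spacer = site.protospacer if site.protospacer[0] == "G" else "G" + site.protospacer[1:]
        if spacer in spacer_map:
            raise ValueError(
                f"duplicate spacer for sites {spacer_map[spacer].site_id} "
                f"and {site.site_id}"
            )
        spacer_map[spacer] = site

    if not isinstance(reads, dict):
        reads = {"rep1": reads}

    ds = ScreenDataset(sites=list(library), metadata=metadata or {})
    for rep, records in reads.items():
        seqs = Counter(
            str(r.seq) if hasattr(r, "seq") else str(r) for r in records
        )
        ds.unassigned.setdefault(rep, 0)
        for seq, n in seqs.items():
            idx = seq.find(scaffold)
            if idx < 20:
                ds.unassigned[rep] += n
                continue
            spacer = seq[idx - 20:idx]
            site = spacer_map.get(spacer)
            if site is None:
                ds.unassigned[rep] += n
                continue
            cassette = seq[idx + len(scaffold):]
            used5 = min(flank_len, len(site.flank5))
            used3 = min(flank_len, len(site.flank3))
            expected_len = used5 + 20 + 3 + used3
            site_other = ds.other.setdefault(site.site_id, {})
            if len(cassette) != expected_len:
                site_other[rep] = site_other.get(rep, 0) + n
                continue
            region = cassette[used5:used5 + 20]
            edits, bad = [], 0
            for i, (a, b) in enumerate(zip(site.protospacer, region)):
                if a == b:
                    continue
                if a == "A" and b == "G":
                    edits.append(i + 1)
                else:
                    bad += 1
            if bad > mismatch_budget:
                site_other[rep] = site_other.get(rep, 0) + n
                continue
            outcome = apply_edits(site.protospacer, edits)
            table = ds.counts.setdefault(site.site_id, {}).setdefault(rep, {})
            table[outcome] = table.get(outcome, 0) + n
    return ds


def filter_sites(ds: ScreenDataset, min_reads: int = 100,
                 min_replicates: int = 2) -> ScreenDataset:
    """Keep sites with ≥ min_reads assigned reads in ≥ min_replicates replicates."""
    keep = []
    for s in ds.sites:
        ok = sum(
            1 for rep in ds.counts.get(s.site_id, {})
            if ds.assigned_reads(s.site_id, rep) >= min_reads
        )
        if ok >= min_replicates or min_reads == 0:
            keep.append(s.site_id)
    removed = len(ds.sites) - len(keep)
    if removed:
        logger.info("filter_sites removed %d of %d sites", removed, len(ds.sites))
    return ds.subset(keep)


def replicate_correlation(ds: ScreenDataset) -> dict[str, pd.DataFrame]:
    """Pairwise Spearman/Pearson matrices over per-site total efficiencies."""
    reps = ds.replicates
    if len(reps) < 2:
        raise ValueError("need ≥2 replicates for correlation")
    series = {r: ds.efficiency_series(r) for r in reps}
    out = {m: pd.DataFrame(np.eye(len(reps)), index=reps, columns=reps)
           for m in ("spearman", "pearson")}
    for i, a in enumerate(reps):
        for b in reps[i + 1:]:
            shared = series[a].index.intersection(series[b].index)
            if len(shared) < 2:
                raise ValueError(f"replicates {a}/{b} share <2 sites")
            x, y = series[a][shared], series[b][shared]
            rs = stats.spearmanr(x, y).statistic
            rp = stats.pearsonr(x, y).statistic
            for m, v in (("spearman", rs), ("pearson", rp)):
                out[m].loc[a, b] = out[m].loc[b, a] = v
    return out


def pam_matrix(ds: ScreenDataset) -> pd.DataFrame:
    """4×16 table of mean total efficiency: rows = PAM nt 1, cols = nt 2+3.

    Cells with no site are NaN (flagged empty), never zero-filled.
    """
    eff = ds.efficiency_series()
    rows = []
    for s in ds.sites:
        if s.site_id in eff.index:
            rows.append((s.pam3[0], s.pam3[1:], eff[s.site_id]))
    df = pd.DataFrame(rows, columns=["n1", "n23", "eff"])
    mat = pd.DataFrame(np.nan, index=list(NUCS), columns=DINUCS)
    if len(df):
        grouped = df.groupby(["n1", "n23"])["eff"].mean()
        for (n1, n23), v in grouped.items():
            mat.loc[n1, n23] = v
    return mat


def editing_window(ds: ScreenDataset, pam_filter=None) -> pd.Series:
    """Mean per-position A→G rate over sites (positions 1-20).

    The denominator at each position counts only sites that carry an adenine
    there; positions never containing an A report NaN ("no data"), not 0.
    """
    if pam_filter is not None:
        classes = resolve_pam_classes(
            pam_filter if isinstance(pam_filter, (list, tuple, set)) else [pam_filter]
        )
        sites = [s for s in ds.sites if any(c.matches(s.pam3) for c in classes)]
    else:
        sites = ds.sites
    sums = np.zeros(20)
    denom = np.zeros(20)
    for s in sites:
        dist = ds.distribution(s.site_id)
        if dist is None:
            continue
        pp = per_position_efficiency(dist)
        mask = np.array([c == "A" for c in s.protospacer])
        sums[mask] += pp[mask]
        denom[mask] += 1
    with np.errstate(invalid="ignore"):
        vals = np.where(denom > 0, sums / np.maximum(denom, 1), np.nan)
    return pd.Series(vals, index=np.arange(1, 21), name="mean_AtoG_rate")


def window_fwhm(window: pd.Series) -> float:
    """Full width at half maximum of an estimated editing window (positions)."""
    v = window.to_numpy(dtype=float)
    v = np.nan_to_num(v, nan=0.0)
    half = v.max() / 2.0
    return float(np.sum(v >= half))


def trinucleotide_preference(ds: ScreenDataset) -> dict[str, dict[str, float]]:
    """Motif (5'N-A-3'N) proportions among sites above vs below mean efficiency.

    The split threshold is the dataset mean total efficiency; a site exactly at
    the mean contributes to both splits.
    """
    eff = ds.efficiency_series()
    if eff.empty:
        return {"above": {}, "below": {}}
    mean = eff.mean()
    splits = {"above": [], "below": []}
    for s in ds.sites:
        if s.site_id not in eff.index:
            continue
        motif = s.context_motif()
        e = eff[s.site_id]
        if e >= mean:
            splits["above"].append(motif)
        if e <= mean:
            splits["below"].append(motif)
    out = {}
    for key, motifs in splits.items():
        c = Counter(motifs)
        total = sum(c.values())
        out[key] = {m: n / total for m, n in sorted(c.items())} if total else {}
    return out


@dataclass(frozen=True)
class BystanderCall:
    """Correction-quality call for one site at fixed on-target/bystander cut-offs."""

    site_id: str
    category: str               # corrected_no_bystander | corrected_with_bystander | not_corrected
    on_target_eff: float
    worst_nonsilent_bystander_eff: float
    frame_known: bool = True


def _codon_change_is_silent(site: TargetSite, pos: int) -> bool | None:
    """Whether the A→G edit at protospacer position ``pos`` is synonymous.

    Returns None when the reading frame is unknown or the codon is not fully
    covered by the available sequence context (treated as non-silent upstream).
    Codons are read on the protospacer strand using the stored frame phase of
    protospacer position 1.
    """
    if site.frame_offset == "noncoding":
        return None
    ext = site.flank5 + site.protospacer + site.pam3 + site.flank3
    idx = len(site.flank5) + pos - 1
    phase = (int(site.frame_offset) + pos - 1) % 3
    start = idx - phase
    if start < 0 or start + 3 > len(ext):
        return None
    codon = ext[start:start + 3]
    edited = codon[:phase] + "G" + codon[phase + 1:]
    return str(Seq(codon).translate()) == str(Seq(edited).translate())


def classify_bystanders(ds: ScreenDataset, on_cut: float = 0.10,
                        bys_cut: float = 0.005) -> list[BystanderCall]:
    """Classify each site as corrected with/without non-silent bystanders.

    On-target efficiency is the per-position rate at the target adenine; the
    bystander score is the worst single non-silent bystander rate.  Sites below
    ``on_cut`` on target are "not_corrected" regardless of bystanders.
    Synonymous bystander edits are ignored; sites without frame annotation are
    classified conservatively (every bystander counted) and flagged.
    """
    calls = []
    for s in ds.sites:
        dist = ds.distribution(s.site_id)
        if dist is None:
            continue
        pp = per_position_efficiency(dist)
        on_eff = float(pp[s.target_pos - 1])
        frame_known = s.frame_offset != "noncoding"
        worst = 0.0
        for p in s.a_positions:
            if p == s.target_pos:
                continue
            silent = _codon_change_is_silent(s, p)
            if silent is True:
                continue
            worst = max(worst, float(pp[p - 1]))
        if on_eff < on_cut:
            cat = "not_corrected"
        elif worst <= bys_cut:
            cat = "corrected_no_bystander"
        else:
            cat = "corrected_with_bystander"
        calls.append(BystanderCall(s.site_id, cat, on_eff, worst, frame_known))
    return calls


def mutation_rollup(ds: ScreenDataset, calls: list[BystanderCall]) -> pd.DataFrame:
    """Per-mutation summary: does ANY sgRNA achieve corrected_no_bystander?"""
    gene_of = {s.site_id: s.gene_id for s in ds.sites}
    df = pd.DataFrame([
        {"gene_id": gene_of[c.site_id], "site_id": c.site_id, "category": c.category}
        for c in calls
    ])
    if df.empty:
        return pd.DataFrame(columns=["gene_id", "n_sites", "any_clean_correction"])
    g = df.groupby("gene_id")
    return pd.DataFrame({
        "n_sites": g.size(),
        "any_clean_correction": g["category"].apply(
            lambda col: bool((col == "corrected_no_bystander").any())
        ),
    }).reset_index()


# ---------------------------------------------------------------------------
# serialization

def counts_to_frame(ds: ScreenDataset) -> pd.DataFrame:
    rows = []
    for site_id, per_rep in ds.counts.items():
        for rep, table in per_rep.items():
            for o, n in sorted(table.items(), key=lambda kv: kv[0].positions):
                rows.append((site_id, rep, o.label(), o.sequence, n))
    for site_id, per_rep in ds.other.items():
        for rep, n in per_rep.items():
            rows.append((site_id, rep, "OTHER", "", n))
    return pd.DataFrame(rows, columns=["site_id", "replicate", "outcome", "sequence", "count"])


def write_counts_tsv(ds: ScreenDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write("# bekit counts v1\n")
        counts_to_frame(ds).to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path, sites) -> ScreenDataset:
    df = pd.read_csv(path, sep="\t", comment="#")
    ds = ScreenDataset(sites=list(sites))
    by_id = {s.site_id: s for s in sites}
    for row in df.itertuples(index=False):
        if row.site_id not in by_id:
            continue
        if row.outcome == "OTHER":
            ds.other.setdefault(row.site_id, {})[str(row.replicate)] = int(row.count)
            continue
        o = Outcome.from_label(row.outcome, by_id[row.site_id].protospacer)
        table = ds.counts.setdefault(row.site_id, {}).setdefault(str(row.replicate), {})
        table[o] = int(row.count)
    return ds


def site_summary_frame(ds: ScreenDataset) -> pd.DataFrame:
    """Per-site, per-replicate totals and per-position rates (tidy TSV shape)."""
    rows = []
    for s in ds.sites:
        for rep in ds.counts.get(s.site_id, {}):
            dist = ds.distribution(s.site_id, rep)
            if dist is None:
                continue
            pp = per_position_efficiency(dist)
            row = {
                "site_id": s.site_id, "gene_id": s.gene_id, "replicate": rep,
                "pam": s.pam3, "target_pos": s.target_pos,
                "n_reads": ds.assigned_reads(s.site_id, rep),
                "total_eff": total_efficiency(dist),
            }
            row.update({f"pos{p}": pp[p - 1] for p in range(1, 21)})
            rows.append(row)
    return pd.DataFrame(rows)
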