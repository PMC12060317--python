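"""Quantification and screen summaries against brute-force oracles and the
simulator's ground truth."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bekit.outcomes import apply_edits, per_position_efficiency
from bekit.screen import (
    ScreenDataset,
    classify_bystanders,
    count_outcomes,
    editing_window,
    filter_sites,
    mutation_rollup,
    pam_matrix,
    read_counts_tsv,
    replicate_correlation,
    site_summary_frame,
    trinucleotide_preference,
    window_fwhm,
    write_counts_tsv,
)
from bekit.seqcore import DEFAULT_SCAFFOLD, TargetSite
from bekit.simulate import (
    DoseModel,
    EditorProfile,
    generate_screen,
    reads_from_counts,
    synthesize_read,
    true_site_distribution,
)


def make_site(site_id, protospacer, pam="AGGT", target_pos=6, gene="g1", **kw):
    kw.setdefault("flank5", "ACGTACGTACGTACGTACGT")
    kw.setdefault("flank3", "TGCATGCATGCATGCATGCA")
    return TargetSite(site_id, gene, protospacer, pam, target_pos=target_pos, **kw)


def dataset_from_effs(effs: dict, pams: dict | None = None,
                      protos: dict | None = None, depth=1000):
    """Single-A sites with exact efficiencies, one replicate."""
    sites, counts = [], {}
    for sid, e in effs.items():
        proto = (protos or {}).get(sid, "CCCCCACCCCCCCCCCCCCC")
        s = make_site(sid, proto, pam=(pams or {}).get(sid, "AGGT"), gene=sid)
        sites.append(s)
        wt = apply_edits(proto, ())
        ed = apply_edits(proto, [6])
        n_ed = int(round(e * depth))
        counts[sid] = {"rep1": {wt: depth - n_ed, ed: n_ed}}
    return ScreenDataset(sites=sites, counts=counts)


# -- count_outcomes -----------------------------------------------------------

def test_unedited_read_counts_as_unedited():
    s = make_site("s1", "GACCCACCCCCCCCCCCCCC")
    read = synthesize_read(s, apply_edits(s.protospacer, ()), DEFAULT_SCAFFOLD, 10)
    ds = count_outcomes([read], [s], DEFAULT_SCAFFOLD, flank_len=10)
    wt = apply_edits(s.protospacer, ())
    assert ds.counts["s1"]["rep1"][wt] == 1
    assert ds.unassigned["rep1"] == 0


def test_insertion_goes_to_other_bucket():
    s = make_site("s1", "GACCCACCCCCCCCCCCCCC")
    read = synthesize_read(s, apply_edits(s.protospacer, [6]), DEFAULT_SCAFFOLD, 10)
    idx = read.find(DEFAULT_SCAFFOLD) + len(DEFAULT_SCAFFOLD) + 12
    mutated = read[:idx] + "T" + read[idx:]     # 1-nt insertion in the cassette
    ds = count_outcomes([mutated], [s], DEFAULT_SCAFFOLD, flank_len=10)
    assert ds.other["s1"]["rep1"] == 1
    assert ds.counts.get("s1", {}) == {}


def test_mismatch_budget():
    s = make_site("s1", "GACCCACCCCCCCCCCCCCC")
    read = synthesize_read(s, apply_edits(s.protospacer, [6]), DEFAULT_SCAFFOLD, 10)
    idx = read.find(DEFAULT_SCAFFOLD) + len(DEFAULT_SCAFFOLD) + 10
    one_mm = read[:idx + 2] + "T" + read[idx + 3:]    # C->T inside protospacer
    ds = count_outcomes([one_mm], [s], DEFAULT_SCAFFOLD, flank_len=10)
    assert sum(ds.counts["s1"]["rep1"].values()) == 1  # within default budget 1
    ds0 = count_outcomes([one_mm], [s], DEFAULT_SCAFFOLD, mismatch_budget=0,
                         flank_len=10)
    assert ds0.other["s1"]["rep1"] == 1


def test_duplicate_spacers_rejected():
    s1 = make_site("a", "GACCCACCCCCCCCCCCCCC")
    s2 = make_site("b", "GACCCACCCCCCCCCCCCCC")
    with pytest.raises(ValueError, match="duplicate spacer"):
        count_outcomes([], [s1, s2], DEFAULT_SCAFFOLD)


def test_read_total_conservation_and_recovery():
    """Simulator round-trip: reads -> counts recovers per-site frequencies."""
    ds, truth = generate_screen(30, depth=2000, replicates=2, noise_sd=0.0, seed=13)
    reads = {"rep1": [], "rep2": []}
    for rep, read in reads_from_counts(ds, DEFAULT_SCAFFOLD, flank_len=16):
        reads[rep].append(read)
    total_in = {rep: len(r) for rep, r in reads.items()}
    ds2 = count_outcomes(reads, ds.sites, DEFAULT_SCAFFOLD, flank_len=16)
    for rep in ("rep1", "rep2"):
        assigned = sum(sum(t.values()) for per in ds2.counts.values()
                       for r, t in per.items() if r == rep)
        other = sum(n for per in ds2.other.values()
                    for r, n in per.items() if r == rep)
        assert assigned + other + ds2.unassigned[rep] == total_in[rep]
    # exact recovery (reads were synthesized losslessly)
    for sid, per in ds.counts.items():
        for rep, table in per.items():
            assert ds2.counts[sid][rep] == table


# -- filter_sites -------------------------------------------------------------

def test_filter_identity_and_removal(small_screen):
    ds, _ = small_screen
    assert len(filter_sites(ds, 0, 0).sites) == len(ds.sites)
    strict = filter_sites(ds, 10 ** 9, 1)
    assert strict.sites == []


def test_filter_idempotent(small_screen):
    ds, _ = small_screen
    once = filter_sites(ds, 1000, 2)
    twice = filter_sites(once, 1000, 2)
    assert [s.site_id for s in once.sites] == [s.site_id for s in twice.sites]


# -- replicate correlation ----------------------------------------------------

def test_duplicated_replicate_perfect_correlation():
    ds = dataset_from_effs({"a": 0.1, "b": 0.5, "c": 0.9})
    for sid in list(ds.counts):
        ds.counts[sid]["rep2"] = dict(ds.counts[sid]["rep1"])
    out = replicate_correlation(ds)
    assert out["spearman"].iloc[0, 1] == pytest.approx(1.0)
    assert out["pearson"].iloc[0, 1] == pytest.approx(1.0)


def test_anti_ordered_replicates():
    ds = dataset_from_effs({"a": 0.1, "b": 0.5, "c": 0.9})
    flipped = dataset_from_effs({"a": 0.9, "b": 0.5, "c": 0.1})
    for sid in list(ds.counts):
        ds.counts[sid]["rep2"] = flipped.counts[sid]["rep1"]
    assert replicate_correlation(ds)["spearman"].iloc[0, 1] == pytest.approx(-1.0)


def test_correlation_matches_manual_ranks(small_screen):
    ds, _ = small_screen
    out = replicate_correlation(ds)["spearman"]
    e1 = ds.efficiency_series("rep1")
    e2 = ds.efficiency_series("rep2")
    shared = e1.index.intersection(e2.index)
    # independent implementation: Pearson of average ranks
    r1 = pd.Series(e1[shared]).rank().to_numpy()
    r2 = pd.Series(e2[shared]).rank().to_numpy()
    manual = np.corrcoef(r1, r2)[0, 1]
    assert out.loc["rep1", "rep2"] == pytest.approx(manual, abs=1e-12)


def test_correlation_needs_two_replicates():
    ds = dataset_from_effs({"a": 0.1, "b": 0.5})
    with pytest.raises(ValueError, match="replicates"):
        replicate_correlation(ds)


# -- PAM matrix ---------------------------------------------------------------

def test_pam_matrix_single_cell():
    ds = dataset_from_effs({"a": 0.5, "b": 0.5}, pams={"a": "AGGT", "b": "AGGT"})
    mat = pam_matrix(ds)
    assert mat.loc["A", "GG"] == pytest.approx(0.5)
    assert mat.drop(columns="GG").isna().all().all()


def test_pam_matrix_matches_groupby_oracle(small_screen):
    ds, _ = small_screen
    mat = pam_matrix(ds)
    eff = ds.efficiency_series()
    groups = {}
    for s in ds.sites:
        if s.site_id in eff.index:
            groups.setdefault(s.pam3, []).append(eff[s.site_id])
    for pam, vals in groups.items():
        assert mat.loc[pam[0], pam[1:]] == pytest.approx(np.mean(vals))
    # cells with no sites stay NaN
    empty = [(r, c) for r in mat.index for c in mat.columns
             if r + c not in groups]
    assert all(np.isnan(mat.loc[r, c]) for r, c in empty)


def test_nrn_cells_exceed_nyn_under_spry_profile():
    ds, _ = generate_screen(300, depth=3000, replicates=2, noise_sd=0.0, seed=17)
    mat = pam_matrix(ds)
    nrn = [mat.loc[r, c] for r in mat.index for c in mat.columns
           if c[0] in "AG" and np.isfinite(mat.loc[r, c])]
    nyn = [mat.loc[r, c] for r in mat.index for c in mat.columns
           if c[0] in "CT" and np.isfinite(mat.loc[r, c])]
    assert np.mean(nrn) > 2 * np.mean(nyn)


# -- editing window -----------------------------------------------------------

def test_window_equals_mask_for_single_fully_edited_site():
    proto = "CCCAAACCCCCCCCCCCCCC"
    s = make_site("s1", proto, target_pos=4)
    full = apply_edits(proto, [4, 5, 6])
    ds = ScreenDataset(sites=[s], counts={"s1": {"rep1": {full: 100}}})
    win = editing_window(ds)
    assert win[4] == win[5] == win[6] == pytest.approx(1.0)
    assert win.drop([4, 5, 6]).isna().all()    # no As elsewhere -> no data


def test_window_width_ranking_recovers_profiles():
    wide, _ = generate_screen(400, EditorProfile.abe8e_like(),
                              DoseModel.mrna_like(), depth=3000,
                              replicates=2, noise_sd=0.0, seed=19)
    narrow, _ = generate_screen(0, EditorProfile.abemax_like(),
                                DoseModel.mrna_like(), depth=3000,
                                replicates=2, noise_sd=0.0, seed=19,
                                sites=wide.sites)
    f_wide = window_fwhm(editing_window(wide, "NRN"))
    f_narrow = window_fwhm(editing_window(narrow, "NRN"))
    assert f_wide > f_narrow


# -- trinucleotide preference -------------------------------------------------

def test_single_motif_dominates_both_splits():
    protos = {"a": "CCCCTACCCCCCCCCCCCCC", "b": "CCCCTACCCCCCCCCCCCCC"}
    ds = dataset_from_effs({"a": 0.2, "b": 0.6}, protos=protos)
    prefs = trinucleotide_preference(ds)
    assert prefs["above"] == {"TAC": 1.0}
    assert prefs["below"] == {"TAC": 1.0}


def test_preference_matches_tabulation(small_screen):
    ds, _ = small_screen
    prefs = trinucleotide_preference(ds)
    eff = ds.efficiency_series()
    mean = eff.mean()
    above = Counter(s.context_motif() for s in ds.sites
                    if s.site_id in eff.index and eff[s.site_id] >= mean)
    total = sum(above.values())
    for motif, frac in prefs["above"].items():
        assert frac == pytest.approx(above[motif] / total)
    assert sum(prefs["above"].values()) == pytest.approx(1.0)
    assert sum(prefs["below"].values()) == pytest.approx(1.0)


# -- bystander classification -------------------------------------------------

def single_a_call(on_eff, bys_eff, silent=False):
    """Two-A site: target at 6, bystander at 9; frame chosen for silent/non-silent."""
    proto = "CCCCCACCACCCCCCCCCCC"
    # frame 0: position 1 starts a codon; bystander A at 9 is codon (7,8,9) 3rd base
    # CCA->CCG is silent (Pro); frame 1 makes it ACC->GCC (Thr->Ala), non-silent
    frame = 0 if silent else 1
    s = make_site("s1", proto, target_pos=6, frame_offset=frame)
    wt = apply_edits(proto, ())
    on = apply_edits(proto, [6])
    bys = apply_edits(proto, [6, 9])
    n = 10000
    n_bys = int(round(bys_eff * n))
    n_on = int(round(on_eff * n)) - n_bys
    counts = {"s1": {"rep1": {wt: n - n_on - n_bys, on: n_on, bys: n_bys}}}
    ds = ScreenDataset(sites=[s], counts=counts)
    return classify_bystanders(ds)[0]


def test_clean_correction():
    call = single_a_call(0.40, 0.001)
    assert call.category == "corrected_no_bystander"
    assert call.on_target_eff == pytest.approx(0.40, abs=1e-6)


def test_low_on_target_is_not_corrected_regardless():
    assert single_a_call(0.05, 0.04).category == "not_corrected"


def test_bystander_above_cutoff():
    assert single_a_call(0.40, 0.05).category == "corrected_with_bystander"


def test_silent_bystanders_ignored():
    call = single_a_call(0.40, 0.05, silent=True)
    assert call.category == "corrected_no_bystander"
    assert call.worst_nonsilent_bystander_eff == 0.0


def test_silent_call_against_codon_oracle():
    """The silent/non-silent decision agrees with direct codon translation."""
    from Bio.Seq import Seq
    proto = "CCCCCACCACCCCCCCCCCC"
    # frame 0, codons from position 1: CCC CCA CCA CCC ...
    codon = proto[6:9]                  # positions 7-9 = CCA
    edited = codon[:2] + "G"
    assert str(Seq(codon).translate()) == str(Seq(edited).translate())  # P==P


def test_noncoding_sites_conservative_and_flagged():
    proto = "CCCCCACCACCCCCCCCCCC"
    s = make_site("s1", proto, target_pos=6, frame_offset="noncoding")
    wt = apply_edits(proto, ())
    bys = apply_edits(proto, [6, 9])
    ds = ScreenDataset(sites=[s], counts={"s1": {"rep1": {wt: 80, bys: 20}}})
    call = classify_bystanders(ds)[0]
    assert not call.frame_known
    assert call.category == "corrected_with_bystander"


def test_bystander_monotone_in_cutoff(small_screen):
    ds, _ = small_screen
    loose = {c.site_id: c.category for c in classify_bystanders(ds, bys_cut=0.05)}
    strict = {c.site_id: c.category for c in classify_bystanders(ds, bys_cut=0.001)}
    for sid, cat in strict.items():
        if cat == "corrected_no_bystander":
            assert loose[sid] == "corrected_no_bystander"


def test_mutation_rollup(small_screen):
    ds, _ = small_screen
    calls = classify_bystanders(ds)
    roll = mutation_rollup(ds, calls)
    by_gene = {}
    for c in calls:
        g = ds.site(c.site_id).gene_id
        by_gene.setdefault(g, []).append(c.category)
    for row in roll.itertuples(index=False):
        assert row.any_clean_correction == (
            "corrected_no_bystander" in by_gene[row.gene_id])


# -- serialization ------------------------------------------------------------

def test_counts_tsv_roundtrip(tmp_path, small_screen):
    ds, _ = small_screen
    path = tmp_path / "counts.tsv"
    write_counts_tsv(ds, path)
    back = read_counts_tsv(path, ds.sites)
    assert back.counts.keys() == ds.counts.keys()
    for sid in ds.counts:
        assert back.counts[sid] == ds.counts[sid]


def test_site_summary_frame(small_screen):
    ds, _ = small_screen
    df = site_summary_frame(ds)
    assert {"site_id", "replicate", "total_eff"} <= set(df.columns)
    row = df.iloc[0]
    assert row["total_eff"] == pytest.approx(
        ds.total_efficiency(row["site_id"], row["replicate"]))
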