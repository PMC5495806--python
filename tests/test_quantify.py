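"""PSM filtering, ratio computation, rollups and picked protein FDR."""

import numpy as np
import pandas as pd
import pytest

import hiriefquant as hq
from hiriefquant.quantify import (
    DEFAULT_DESIGN,
    ImpurityMatrix,
    intensity_columns,
    normalized_columns,
    ratio_columns,
)

CH = DEFAULT_DESIGN.channels


def make_psm(intensities, n_phospho=1, localization=99.0, **overrides):
    row = {
        "arm": "phospho" if n_phospho else "standard",
        "peptide": "SAMPLESEQK",
        "protein_id": "SYN0001",
        "gene": "GENE0001",
        "peptide_start": 1,
        "mod_positions": "1" if n_phospho else "",
        "n_phospho": n_phospho,
        "localization_score": localization if n_phospho else np.nan,
        "precursor_area": 1e5,
        "fraction": 10,
        "strip": "wide-range",
    }
    for ch, v in zip(CH, intensities):
        row[f"tmt_{ch}"] = v
    row.update(overrides)
    return row


class TestFilterPsms:
    def test_zero_reporter_rejected(self):
        psms = pd.DataFrame([make_psm([100.0] * 9 + [0.0])])
        kept, rejected = hq.filter_psms(psms)
        assert kept.empty
        assert rejected["reject_reason"].tolist() == ["incomplete reporter set"]

    @pytest.mark.parametrize("score,kept_expected", [(94.9, False), (95.0, True)])
    def test_localization_boundary(self, score, kept_expected):
        psms = pd.DataFrame([make_psm([100.0] * 10, localization=score)])
        kept, _ = hq.filter_psms(psms)
        assert (len(kept) == 1) is kept_expected

    def test_localization_not_applied_to_non_phospho(self):
        psms = pd.DataFrame([make_psm([100.0] * 10, n_phospho=0)])
        kept, _ = hq.filter_psms(psms)
        assert len(kept) == 1


class TestImpurityCorrection:
    def test_identity_matrix_is_noop(self):
        v = np.array([1.0, 5, 2, 8, 3, 9, 4, 7, 6, 10])
        out = hq.correct_impurities(v, ImpurityMatrix.identity())
        assert np.allclose(out, v)

    def test_inverts_forward_mixing(self):
        rng = np.random.default_rng(0)
        m = ImpurityMatrix.two_isotope()
        for _ in range(50):
            x_true = rng.uniform(0, 1e6, size=10)
            observed = m.mix(x_true)
            assert np.allclose(
                hq.correct_impurities(observed, m), x_true, atol=1e-9 * 1e6
            )

    def test_two_channel_toy_hand_solved(self):
        # 5% symmetric spill: m = [[.95,.05],[.05,.95]], det = 0.9
        m = ImpurityMatrix(
            np.array([[0.95, 0.05], [0.05, 0.95]]), channels=("A", "B")
        )
        observed = np.array([100.0, 200.0])
        expected = np.array(
            [(0.95 * 100 - 0.05 * 200) / 0.9, (0.95 * 200 - 0.05 * 100) / 0.9]
        )
        assert np.allclose(hq.correct_impurities(observed, m), expected)

    def test_negative_components_clamped(self):
        m = ImpurityMatrix(
            np.array([[0.9, 0.3], [0.1, 0.7]]), channels=("A", "B")
        )
        out = hq.correct_impurities([10.0, 1.0], m)
        assert (out >= 0).all()

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ImpurityMatrix(np.array([[1.0, -0.1], [0.0, 1.0]]), channels=("A", "B"))
        with pytest.raises(ValueError, match="column sums"):
            ImpurityMatrix(np.array([[1.0, 0.2], [0.3, 0.9]]), channels=("A", "B"))


class TestPsmRatios:
    def test_all_equal_gives_unit_ratios(self):
        psms = pd.DataFrame([make_psm([250.0] * 10)])
        out = hq.psm_ratios(psms)
        assert np.allclose(out[ratio_columns()].to_numpy(), 1.0)

    def test_treated_double_gives_ratio_two(self):
        intens = [100.0] * 10
        intens[5] = 200.0  # 129N, pervanadate
        out = hq.psm_ratios(pd.DataFrame([make_psm(intens)]))
        assert out["ratio_129N"].iloc[0] == pytest.approx(2.0)

    def test_control_ratios_average_to_one(self):
        rng = np.random.default_rng(1)
        psms = pd.DataFrame(
            [make_psm(rng.uniform(10, 1000, size=10)) for _ in range(20)]
        )
        out = hq.psm_ratios(psms)
        ctrl = out[ratio_columns(DEFAULT_DESIGN.control_channels)].mean(axis=1)
        assert np.allclose(ctrl, 1.0)


class TestRollups:
    def test_site_median(self):
        rows = []
        for scale in (1.0, 2.0, 4.0):
            intens = [100.0] * 10
            intens[9] = 100.0 * scale
            rows.append(make_psm(intens))
        psms = hq.psm_ratios(pd.DataFrame(rows))
        sites = hq.rollup_sites(psms)
        assert len(sites) == 1
        assert sites["ratio_131"].iloc[0] == pytest.approx(2.0)
        assert sites["n_supporting_psms"].iloc[0] == 3

    def test_missed_cleavage_peptides_share_site_key(self):
        # same protein position reached through two peptides
        a = make_psm([100.0] * 10, peptide="SAK", peptide_start=5, mod_positions="1")
        b = make_psm(
            [100.0] * 10, peptide="GGSAK", peptide_start=3, mod_positions="3"
        )
        psms = hq.psm_ratios(pd.DataFrame([a, b]))
        sites = hq.rollup_sites(psms)
        assert len(sites) == 1
        assert sites["position"].iloc[0] == 5
        assert sites["residue"].iloc[0] == "S"

    def test_subset_rollups_differ_as_constructed(self):
        singly = make_psm([100.0] * 10, mod_positions="1", n_phospho=1)
        intens = [100.0] * 10
        intens[9] = 400.0
        multiply = make_psm(intens, mod_positions="1;4", n_phospho=2)
        psms = hq.psm_ratios(pd.DataFrame([singly, multiply]))
        s = hq.rollup_sites(psms, subset="singly")
        m = hq.rollup_sites(psms, subset="multiply")
        site_s = s[(s["position"] == 1)]
        site_m = m[(m["position"] == 1)]
        assert site_s["ratio_131"].iloc[0] == pytest.approx(1.0)
        assert site_m["ratio_131"].iloc[0] == pytest.approx(4.0)
        assert m["from_multiply_phosphorylated"].all()

    def test_protein_normalization_centers_channels(self):
        rng = np.random.default_rng(2)
        rows = [
            make_psm(
                rng.uniform(50, 500, size=10),
                n_phospho=0,
                gene=f"G{i}",
                peptide=f"PEP{i}K",
            )
            for i in range(9)
        ]
        psms = hq.psm_ratios(pd.DataFrame(rows))
        proteins = hq.rollup_proteins(psms)
        log2 = proteins[normalized_columns()].to_numpy()
        assert np.allclose(np.median(log2, axis=0), 0.0, atol=1e-12)

    def test_single_gene_single_psm_normalizes_to_zero(self):
        psms = hq.psm_ratios(
            pd.DataFrame([make_psm(np.linspace(100, 1000, 10), n_phospho=0)])
        )
        proteins = hq.rollup_proteins(psms)
        assert np.allclose(proteins[normalized_columns()].to_numpy(), 0.0)

    def test_spiked_channel_shift_removed(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(8):
            intens = rng.uniform(100, 200, size=10)
            intens[9] *= 2.0  # +1 log2 on channel 131 for every PSM
            rows.append(
                make_psm(intens, n_phospho=0, gene=f"G{i}", peptide=f"PEP{i}K")
            )
        proteins = hq.rollup_proteins(hq.psm_ratios(pd.DataFrame(rows)))
        assert np.median(proteins["normalized_log2_131"]) == pytest.approx(0.0, abs=1e-12)

    def test_normalize_sites_subtracts_protein_log2(self):
        site = pd.DataFrame(
            {
                "gene": ["G1"],
                "protein_id": ["P1"],
                "position": [5],
                "residue": ["S"],
                **{c: [2.0] for c in ratio_columns()},
            }
        )
        proteins = pd.DataFrame(
            {"gene": ["G1"], **{c: [0.4] for c in normalized_columns()}}
        )
        normalized, dropped = hq.normalize_sites_to_protein(site, proteins)
        assert dropped.empty
        assert np.allclose(
            normalized[normalized_columns()].to_numpy(), 1.0 - 0.4
        )

    def test_site_without_protein_dropped_and_counted(self):
        site = pd.DataFrame(
            {
                "gene": ["G1", "G2"],
                "protein_id": ["P1", "P2"],
                "position": [5, 6],
                "residue": ["S", "T"],
                **{c: [1.0, 1.0] for c in ratio_columns()},
            }
        )
        proteins = pd.DataFrame(
            {"gene": ["G1"], **{c: [0.0] for c in normalized_columns()}}
        )
        normalized, dropped = hq.normalize_sites_to_protein(site, proteins)
        assert len(normalized) == 1 and len(dropped) == 1
        assert dropped["gene"].iloc[0] == "G2"


class TestAreasAndFractions:
    @pytest.mark.parametrize(
        "areas, expected",
        [([10, 5, 3, 1], 6.0), ([10], 10.0), ([4, 4], 4.0)],
    )
    def test_top3_area(self, areas, expected):
        assert hq.top3_area(areas) == expected

    def test_top3_matches_sort_and_slice(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            areas = rng.uniform(0, 1e6, size=rng.integers(1, 10))
            expected = float(np.mean(sorted(areas, reverse=True)[:3]))
            assert hq.top3_area(areas) == pytest.approx(expected)

    def test_fraction_assignment_argmax_and_ties(self):
        psms = pd.DataFrame(
            [
                make_psm([1.0] * 10, peptide="AAK", fraction=10, precursor_area=5.0),
                make_psm([1.0] * 10, peptide="AAK", fraction=12, precursor_area=9.0),
                make_psm([1.0] * 10, peptide="BBK", fraction=9, precursor_area=7.0),
                make_psm([1.0] * 10, peptide="BBK", fraction=4, precursor_area=7.0),
                make_psm([1.0] * 10, peptide="CCK", fraction=33, precursor_area=1.0),
            ]
        )
        assigned = hq.assign_peptide_fraction(psms)
        assert assigned["AAK"] == 12
        assert assigned["BBK"] == 4  # tie broken toward the acidic end
        assert assigned["CCK"] == 33


def picked_fdr_oracle(pairs):
    """Brute-force picked FDR: pick, rank, count, running minimum."""
    kept = []
    for target_score, decoy_score in pairs:
        if target_score >= decoy_score and target_score > decoy_score:
            kept.append((target_score, False))
        else:
            kept.append((decoy_score, True))
    kept.sort(key=lambda t: (-t[0], not t[1]))
    qs = []
    for score, _ in kept:
        decoys = sum(1 for s, d in kept if d and s >= score)
        targets = sum(1 for s, d in kept if not d and s >= score)
        qs.append(decoys / targets if targets else float("inf"))
    for i in range(len(qs) - 2, -1, -1):
        qs[i] = min(qs[i], qs[i + 1])
    return kept, qs


class TestPickedProteinFdr:
    @staticmethod
    def to_scores(pairs):
        out = []
        for i, (t, d) in enumerate(pairs):
            out.append((f"P{i}", t, False))
            out.append((f"decoy_P{i}", d, True))
        return out

    def test_all_targets_win_all_q_zero(self):
        pairs = [(10, 1), (9, 2), (8, 3)]
        result = hq.picked_protein_fdr(self.to_scores(pairs))
        assert not result["is_decoy"].any()
        assert (result["q_value"] == 0).all()

    def test_six_pair_hand_enumeration(self):
        pairs = [(10, 1), (9, 2), (3, 8), (7, 4), (2, 6), (5, 1)]
        result = hq.picked_protein_fdr(self.to_scores(pairs))
        assert result["score"].tolist() == [10, 9, 8, 7, 6, 5]
        assert result["is_decoy"].tolist() == [False, False, True, False, True, False]
        assert result["q_value"].to_numpy() == pytest.approx(
            [0.0, 0.0, 1 / 3, 1 / 3, 0.5, 0.5]
        )

    def test_swapping_scores_removes_target(self):
        pairs = [(10, 1), (9, 2)]
        base = hq.picked_protein_fdr(self.to_scores(pairs))
        swapped = hq.picked_protein_fdr(self.to_scores([(1, 10), (9, 2)]))
        assert "P0" in set(base["protein_id"])
        assert "P0" not in set(swapped["protein_id"])
        assert "decoy_P0" in set(swapped["protein_id"])

    def test_matches_oracle_on_small_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(1, 9))
            pairs = [
                (float(rng.integers(0, 20)), float(rng.integers(0, 20)))
                for _ in range(n)
            ]
            # distinct scores keep the hand oracle's tie handling trivial
            pairs = [(t + 0.01 * i, d + 0.005 + 0.01 * i) for i, (t, d) in enumerate(pairs)]
            result = hq.picked_protein_fdr(self.to_scores(pairs))
            _, qs = picked_fdr_oracle(pairs)
            assert result["q_value"].to_numpy() == pytest.approx(np.array(qs))

    def test_unpaired_decoy_is_error(self):
        with pytest.raises(ValueError, match="without a target"):
            hq.picked_protein_fdr([("P1", 5.0, False), ("decoy_P9", 3.0, True)])


class TestSequenceWindow:
    def test_nterm_padding(self):
        protein = "MSTYABCDEFGHIJK".replace("B", "G").replace("J", "L")
        window = hq.sequence_window(protein, 1)
        assert window == "_______" + protein[:8]
        assert len(window) == 15

    def test_mid_protein_substring(self):
        protein = "ACDEFGHIKLMNPQRSTVWY"
        window = hq.sequence_window(protein, 10)
        assert window == protein[2:17]
        assert window[7] == protein[9]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hq.sequence_window("ACDE", 5)

    def test_pipeline_windows_centered_on_sty(self, noisy_sim, noisy_result):
        windows = noisy_result.sites["sequence_window"]
        assert windows.str.len().eq(15).all()
        assert set(windows.str[7]) <= set("STY")
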