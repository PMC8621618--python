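"""Clone calling: barcode grouping, 80-point consistency rule, rarity filter."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from xfpclone import (
    CloneCaller,
    CloneCallingParams,
    SimulationConfig,
    annotate_barcodes,
    call_clones,
    generate_cohort,
)
from xfpclone._schema import INTENSITY_COLUMNS
from xfpclone.barcoding import barcode_frequency
from xfpclone.clone_calling import (
    apply_rarity_filter,
    check_intensity_consistency,
    group_by_barcode,
)


def _cells(intensity_rows, **cols):
    df = pd.DataFrame(intensity_rows, columns=list(INTENSITY_COLUMNS))
    df.insert(0, "cell_id", cols.get("cell_id", [f"c{i}" for i in range(len(df))]))
    df.insert(1, "animal_id", cols.get("animal_id", "a1"))
    df["section_index"] = cols.get("section_index", 0)
    df["region"] = cols.get("region", "LL")
    df["cell_type"] = cols.get("cell_type", "astrocyte")
    return annotate_barcodes(df)


def _partition(caller, cells):
    labels = caller.labels_
    return {frozenset(cells.loc[labels == k, "cell_id"]) for k in np.unique(labels)}


class TestGroupByBarcode:
    def test_basic_grouping(self):
        rows = [[100.0] + [0.0] * 11] * 2 + [[0.0] * 6 + [100.0] + [0.0] * 5]
        groups = group_by_barcode(_cells(rows))
        sizes = sorted(len(idx) for idx in groups.values())
        assert sizes == [1, 2]

    def test_empty_input(self):
        assert group_by_barcode(pd.DataFrame(columns=["animal_id", "barcode"])) == {}

    def test_noiseless_cohort_groups_equal_truth(self, noiseless_cohort):
        cfg, cells, truth = noiseless_cohort
        coded = annotate_barcodes(cells, cfg.presence_threshold)
        groups = group_by_barcode(coded)
        called = {frozenset(coded.loc[idx, "cell_id"]) for idx in groups.values()}
        expected = {
            frozenset(grp["cell_id"])
            for _, grp in truth.assignments.groupby("progenitor_id")
        }
        assert called == expected


class TestIntensityConsistency:
    def _pair(self, delta):
        rows = [[100.0] + [0.0] * 11, [100.0 + delta] + [0.0] * 11]
        return _cells(rows)

    def test_difference_79_is_consistent(self):
        ok, subs = check_intensity_consistency(self._pair(79.0))
        assert ok and len(subs) == 1

    def test_identical_intensities_consistent(self):
        ok, _ = check_intensity_consistency(self._pair(0.0))
        assert ok

    def test_difference_exactly_80_splits(self):
        """The rule is strict: a difference of 80 breaks siblinghood."""
        ok, subs = check_intensity_consistency(self._pair(80.0))
        assert not ok and len(subs) == 2

    def test_only_barcode_present_reporters_compared(self):
        # below-threshold background differences never split a clone
        rows = [
            [100.0, 30.0] + [0.0] * 10,
            [100.0, 0.0] + [0.0] * 10,  # 30-unit diff on an absent reporter
        ]
        cells = _cells(rows)
        assert cells["barcode"].nunique() == 1
        ok, _ = check_intensity_consistency(
            cells, CloneCallingParams(intensity_tolerance=20.0)
        )
        assert ok

    def test_mean_mode_flags_without_splitting(self):
        ok, subs = check_intensity_consistency(
            self._pair(200.0), CloneCallingParams(consistency_mode="mean")
        )
        assert not ok and len(subs) == 1


class TestRarityFilter:
    def _clones_freq(self, n_rare, n_common):
        rows = [[100.0] + [0.0] * 11] * n_common + [[0.0] * 11 + [100.0]] * n_rare
        cells = _cells(rows)
        freq = barcode_frequency(cells)
        clones = pd.DataFrame(
            {"clone_id": ["a", "b"], "barcode": sorted(cells["barcode"].unique())}
        )
        return clones, freq, cells

    def test_half_percent_is_eligible(self):
        clones, freq, cells = self._clones_freq(n_rare=5, n_common=995)
        out = apply_rarity_filter(clones, freq)
        flags = out.set_index("barcode")["rarity_eligible"]
        rare_code = cells["barcode"].value_counts().idxmin()
        assert flags[rare_code]

    def test_exactly_one_percent_is_ineligible(self):
        clones, freq, cells = self._clones_freq(n_rare=10, n_common=990)
        out = apply_rarity_filter(clones, freq)
        rare_code = cells["barcode"].value_counts().idxmin()
        assert freq.set_index("barcode")["fraction"][rare_code] == 0.01
        assert not out.set_index("barcode")["rarity_eligible"][rare_code]

    def test_single_barcode_dataset_ineligible(self):
        rows = [[100.0] + [0.0] * 11] * 50
        cells = _cells(rows)
        clones = call_clones(cells)
        assert not clones["rarity_eligible"].any()

    def test_missing_barcode_rejected(self):
        clones, freq, _ = self._clones_freq(5, 995)
        with pytest.raises(KeyError):
            apply_rarity_filter(clones.assign(barcode="123456123456"), freq)


class TestCallClones:
    def test_partition_recovery_default_cohort(self, default_called):
        coded, truth, caller = default_called
        ari = adjusted_rand_score(truth.assignments["progenitor_id"], caller.labels_)
        assert ari >= 0.99

    def test_conservation_of_cells(self, default_called):
        coded, _, caller = default_called
        assert caller.clones_["n_cells"].sum() == len(coded)
        assert (caller.labels_ >= 0).all()

    def test_row_order_invariance(self, noiseless_cohort):
        cfg, cells, _ = noiseless_cohort
        coded = annotate_barcodes(cells, cfg.presence_threshold)
        shuffled = coded.sample(frac=1.0, random_state=7).reset_index(drop=True)
        p1 = _partition(CloneCaller().fit(coded), coded)
        p2 = _partition(CloneCaller().fit(shuffled), shuffled)
        assert p1 == p2

    def test_infinite_tolerance_equals_barcode_groups(self, default_called):
        coded, _, _ = default_called
        caller = CloneCaller(intensity_tolerance=1e12).fit(coded)
        assert len(caller.clones_) == coded.groupby(["animal_id", "barcode"]).ngroups

    def test_injected_common_code_never_mixed(self):
        """Colliding progenitors above 1% frequency stay mixed-ineligible."""
        cfg = SimulationConfig(n_progenitors=8, seed=21, noise_sd=0.0)
        cells, truth = generate_cohort(cfg, n_shared_profile=2)
        coded = annotate_barcodes(cells, cfg.presence_threshold)
        shared_code = None
        merged = coded.merge(truth.assignments, on="cell_id")
        shared_code = merged.loc[merged["progenitor_id"] == 0, "barcode"].iloc[0]
        freq = barcode_frequency(coded).set_index("barcode")["fraction"]
        assert freq[shared_code] >= 0.01  # small cohort: the code is common
        clones = call_clones(coded)
        shared = clones[clones["barcode"] == shared_code]
        assert len(shared) >= 1
        assert not shared["rarity_eligible"].any()

    def test_single_clone_passthrough(self):
        rows = [[100.0, 0, 0, 0, 0, 0, 0, 200.0, 0, 0, 0, 0]] * 6
        cells = _cells(rows)
        clones = call_clones(cells)
        assert len(clones) == 1
        assert clones["n_cells"].iloc[0] == 6
        assert sorted(clones["cell_ids"].iloc[0].split(";")) == sorted(cells["cell_id"])

    def test_fragment_flagging(self):
        rows = [[100.0] + [0.0] * 11] * 3  # below the 4-cell minimum
        clones = call_clones(_cells(rows))
        assert clones["fragment"].all()

    def test_ari_monotone_in_noise(self):
        """Less measurement noise never worsens partition recovery."""
        aris = []
        for noise in (16.0, 8.0, 4.0, 0.0):
            cfg = SimulationConfig(n_progenitors=100, noise_sd=noise, seed=33)
            cells, truth = generate_cohort(cfg)
            caller = CloneCaller().fit(annotate_barcodes(cells))
            aris.append(
                adjusted_rand_score(truth.assignments["progenitor_id"], caller.labels_)
            )
        assert all(b >= a - 1e-12 for a, b in zip(aris, aris[1:]))
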