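"""Isotope/adduct/artifact/impurity/metabolite classification logic."""

import numpy as np
import pandas as pd
import pytest

from mzsift import chem
from mzsift.annotate import (annotate_adducts_and_transformations,
                             annotate_features, annotate_isomers,
                             annotate_isotopes, classify_origin)
from mzsift.table import FeatureTable

PBP = chem.ElementalFormula.parse("C14H19NO")


def mini_table(rows, n_samples=6, abund=None, groups=None):
    """rows: list of (name, mz, rt); abund: name -> per-sample abundances."""
    names = [r[0] for r in rows]
    ids = [f"s{i}" for i in range(n_samples)]
    if groups is None:
        groups = ["Blank", "Low", "High"] * (n_samples // 3) \
            if n_samples % 3 == 0 else ["Low"] * n_samples
    ab = pd.DataFrame(
        {sid: [abund[r[0]][i] if abund else 100.0 for r in rows]
         for i, sid in enumerate(ids)}, index=names)
    feats = pd.DataFrame({"mz": [r[1] for r in rows],
                          "rt": [r[2] for r in rows]}, index=names)
    samples = pd.DataFrame({"group": groups,
                            "sample_type": ["incubation"] * n_samples,
                            "injection_index": range(n_samples)}, index=ids)
    return FeatureTable(ab, feats, samples)


class TestIsotopes:
    def test_coeluting_pair_with_c13_spacing(self):
        # the published parent/satellite pair: 218.1540 / 219.1572 at 216 s
        t = mini_table([("p", 218.1540, 216.0), ("i", 219.1572, 216.0)],
                       abund={"p": [1000] * 6, "i": [150] * 6})
        ann = annotate_isotopes(t)
        assert set(ann) == {"i"}
        assert ann["i"].isotope_k == 1
        assert ann["i"].parent_feature == "p"
        spacing_err = abs(219.1572 - 218.1540 - 1.003355) / 219.157 * 1e6
        assert abs(ann["i"].ppm_error) <= 5.0 and spacing_err <= 5.0

    def test_no_link_without_coelution(self):
        t = mini_table([("p", 218.1540, 216.0), ("i", 219.1572, 336.0)],
                       abund={"p": [1000] * 6, "i": [150] * 6})
        assert annotate_isotopes(t) == {}

    def test_isotopologue_triplet_chains_to_anchor(self):
        # the chloride-adduct pattern: satellites at +1.00336 and +2.00671
        t = mini_table([("a", 471.2767, 350.0), ("b", 472.2801, 350.0),
                        ("c", 473.2834, 350.0)],
                       abund={"a": [1000] * 6, "b": [300] * 6, "c": [45] * 6})
        ann = annotate_isotopes(t)
        assert ann["b"].isotope_k == 1 and ann["b"].parent_feature == "a"
        assert ann["c"].isotope_k == 2 and ann["c"].parent_feature == "a"

    def test_ratio_gate_with_known_carbon_count(self):
        # 14 carbons -> M+1/M must be near 0.15; a 0.8 ratio is not a 13C peak
        t = mini_table([("p", 218.1540, 216.0), ("i", 219.1572, 216.0)],
                       abund={"p": [1000] * 6, "i": [800] * 6})
        ann = annotate_isotopes(t, n_carbons_hint={"p": 14})
        assert ann == {}


class TestAdductsAndTransformations:
    def test_chloride_dimer_adduct_recognized(self):
        t = mini_table([("x", 471.2771, 350.0)])
        ann = annotate_adducts_and_transformations(t, PBP)
        assert ann["x"].class_label == "adduct"
        assert ann["x"].rule == "[2M+2H+Cl]+"
        assert abs(ann["x"].ppm_error) <= 5.0

    def test_oxo_shift_recognized(self):
        t = mini_table([("x", 232.1331, 343.0)])
        ann = annotate_adducts_and_transformations(t, PBP)
        assert ann["x"].class_label == "transformation"
        assert ann["x"].rule == "oxo-"

    def test_unmatched_mass_stays_unknown(self):
        t = mini_table([("x", 150.0000, 343.0)])
        assert annotate_adducts_and_transformations(t, PBP) == {}

    def test_degenerate_plus_O_rules_flagged_ambiguous(self):
        # HO- and dihydro-oxo- share the +O delta exactly
        t = mini_table([("x", 234.1489, 114.0)])
        ann = annotate_adducts_and_transformations(t, PBP)
        assert ann["x"].rule in ("HO-", "dihydro-oxo-")
        assert set(ann["x"].ambiguous_with) >= (
            {"HO-", "dihydro-oxo-"} - {ann["x"].rule})


class TestOriginLadder:
    def test_coeluting_shift_is_artifact(self):
        # dehydro-shifted species at the parent's RT, absent from blanks
        assert classify_origin(True, True, False, False, True) == "artifact"

    def test_enzyme_blank_only_is_impurity(self):
        assert classify_origin(True, False, True, False, False) == "impurity"

    def test_substrate_blank_presence_is_contaminant(self):
        assert classify_origin(True, False, True, True, False) == "contaminant"

    def test_dose_responsive_clean_feature_is_metabolite(self):
        assert classify_origin(True, False, False, False, True) == "metabolite"

    def test_missing_blanks_undetermined_not_guessed(self):
        assert classify_origin(True, False, None, False, True) == "undetermined"
        assert classify_origin(True, False, True, None, True) == "undetermined"


class TestIsomers:
    def test_two_hydroxy_matches_numbered_by_rt(self):
        anns = {
            "a": _metab("a", "HO-"), "b": _metab("b", "HO-"),
        }
        t = mini_table([("a", 276.1954, 269.0), ("b", 276.1954, 316.0)])
        out = annotate_isomers(anns, t)
        assert out["a"].isomer_index == 1
        assert out["b"].isomer_index == 2
        assert out["a"].isomer_of == ("b",)

    def test_single_match_gets_no_isomer_link(self):
        anns = {"a": _metab("a", "HO-")}
        t = mini_table([("a", 276.1954, 269.0)])
        out = annotate_isomers(anns, t)
        assert out["a"].isomer_index == 0

    def test_three_matches_numbered_ascending(self):
        anns = {k: _metab(k, "HO-") for k in "abc"}
        t = mini_table([("b", 276.1954, 200.0), ("a", 276.1954, 100.0),
                        ("c", 276.1954, 300.0)])
        out = annotate_isomers(anns, t)
        # a (rt 100) -> 1, b (rt 200) -> 2, c (rt 300) -> 3
        assert [out[k].isomer_index for k in "abc"] == [1, 2, 3]


def _metab(name, rule):
    from mzsift.annotate import Annotation
    return Annotation(name, "metabolite", rule=rule)


class TestEndToEndAnnotation:
    def planted_classes(self, pipeline):
        """Map each significant feature to its planted ledger class."""
        study = pipeline.study
        table = pipeline.filtered_raw
        mono = study.ledger[study.ledger.isotope_k == 0]
        species = mono.groupby(["species", "species_class", "mz",
                                "rt_apex"]).size().reset_index()
        out = {}
        for f in table.feature_names:
            mz = table.features.loc[f, "mz"]
            rt = table.features.loc[f, "rt"]
            hit = species[
                (np.abs(species.mz - mz) / mz * 1e6 <= 5.0)
                & (np.abs(species.rt_apex - rt) <= 10.0)]
            if len(hit):
                out[f] = hit.species_class.iloc[0]
        return out

    def test_planted_metabolite_recall_is_complete(self, pipeline):
        truth = self.planted_classes(pipeline)
        for f, cls in truth.items():
            if cls == "metabolite":
                assert pipeline.annotations[f].class_label == "metabolite", \
                    f"{f}: planted metabolite annotated as " \
                    f"{pipeline.annotations[f].class_label}"

    def test_impurity_and_artifact_never_called_metabolite(self, pipeline):
        truth = self.planted_classes(pipeline)
        for f, cls in truth.items():
            if cls in ("impurity", "artifact", "adduct"):
                assert pipeline.annotations[f].class_label != "metabolite"

    def test_annotation_order_independent_and_idempotent(self, pipeline):
        table = pipeline.filtered_raw
        shuffled = table.subset(list(reversed(table.feature_names)))
        kwargs = dict(
            dose_responsive={f for f, a in pipeline.annotations.items()
                             if a.evidence.get("dose_responsive")},
            noise_floor=pipeline.study.noise_floor)
        a1 = annotate_features(table, PBP, **kwargs)
        a2 = annotate_features(shuffled, PBP, **kwargs)
        assert {f: a.class_label for f, a in a1.items()} == \
            {f: a.class_label for f, a in a2.items()}

    def test_mass_based_annotations_within_tolerance(self, pipeline):
        for a in pipeline.annotations.values():
            if np.isfinite(a.ppm_error):
                assert abs(a.ppm_error) <= 5.0
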