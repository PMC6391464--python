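"""Classify significant features: isotopes, adducts, artifacts, impurities,
metabolites, isomers.

The decision logic mirrors how a metabolism study reads its significant
feature list. 13C isotopologues are recognised by the +1.003355 Da spacing,
co-elution, and lower abundance than their anchor. Remaining features are
matched by mass against (i) an adduct catalogue applied to the parent's
neutral mass and (ii) a biotransformation catalogue applied to the parent
ion. Matched features are then placed by origin evidence in a fixed ladder:

1. mass-shift match that co-elutes with the parent -> in-source artifact;
2. present in the enzyme blank (substrate without microsomes) but absent
   from the substrate blank -> impurity of the drug powder;
3. present in the substrate blank -> contaminant/background;
4. absent from both blanks and dose-responsive -> metabolite.

Features matching the same rule at well-separated retention times are
cross-linked as isomers (covering positional isomers, diastereomers and
conformers alike; MS2-level distinction is out of scope), numbered by
ascending retention time.

Precedence is isotope > adduct > artifact/impurity > metabolite > isomer
linking, so a 13C satellite can never be mistaken for a transformation
match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .chem import (C13_ABUNDANCE, C13_SPACING, ElementalFormula, IonSpecies,
                   PROTONATED, TransformationRule)
from .table import FeatureTable

__all__ = ["Annotation", "annotate_isotopes",
           "annotate_adducts_and_transformations", "classify_origin",
           "annotate_isomers", "annotate_features", "annotation_table"]


@dataclass
class Annotation:
    """Classification of one feature."""

    feature: str
    class_label: str            # parent | isotope | adduct | artifact |
    #                             impurity | metabolite | contaminant |
    #                             endogenous | unknown | undetermined
    parent_feature: str | None = None
    rule: str | None = None     # matched TransformationRule or IonSpecies name
    isotope_k: int = 0
    ppm_error: float = float("nan")
    isomer_index: int = 0       # 1-based when part of an isomer series
    isomer_of: tuple[str, ...] = ()
    ambiguous_with: tuple[str, ...] = ()
    evidence: dict = field(default_factory=dict)

    @property
    def identity(self) -> str:
        """Human-readable identity string in the style of a results table."""
        parts = [self.class_label]
        if self.rule:
            parts.append(f"({self.rule})")
        if self.isotope_k:
            sub = str(self.isotope_k) if self.isotope_k > 1 else ""
            parts.append(f"13C{sub}-isotope")
        if self.isomer_index:
            parts.append(f"isomer {self.isomer_index}")
        return " ".join(parts)


def annotate_isotopes(table: FeatureTable, rt_tol_s: float = 5.0,
                      ppm_tol: float = 5.0, max_k: int = 2,
                      n_carbons_hint: dict[str, int] | None = None,
                      ) -> dict[str, Annotation]:
    """Find 13C isotopologue satellites.

    Feature j is isotope(k) of anchor i when m/z(j) is within ``ppm_tol`` of
    m/z(i) + k * 1.003355, the two co-elute within ``rt_tol_s``, and j is on
    average less abundant than i. Anchors are taken in decreasing mean
    abundance so satellites chain to the monoisotopic feature. When the
    anchor's carbon count is known (``n_carbons_hint``), the observed M+1/M
    abundance ratio must lie within a factor 2 of n_C * 0.0107.
    """
    mz = table.features["mz"]
    rt = table.features["rt"]
    mean_ab = table.abundance.mean(axis=1)
    order = list(mean_ab.sort_values(ascending=False).index)
    out: dict[str, Annotation] = {}
    for anchor in order:
        if anchor in out:
            continue
        for cand in order:
            if cand == anchor or cand in out:
                continue
            if abs(rt[cand] - rt[anchor]) > rt_tol_s:
                continue
            dmz = mz[cand] - mz[anchor]
            if dmz <= 0:
                continue
            k = int(round(dmz / C13_SPACING))
            if not (1 <= k <= max_k):
                continue
            err = (dmz - k * C13_SPACING) / mz[cand] * 1e6
            if abs(err) > ppm_tol:
                continue
            if mean_ab[cand] >= mean_ab[anchor]:
                continue
            if k == 1 and n_carbons_hint and anchor in n_carbons_hint:
                expected = n_carbons_hint[anchor] * C13_ABUNDANCE
                anchor_ab = mean_ab[anchor]
                if anchor_ab > 0:
                    ratio = mean_ab[cand] / anchor_ab
                    if not (expected / 2 <= ratio <= expected * 2):
                        continue
            out[cand] = Annotation(cand, "isotope", parent_feature=anchor,
                                   isotope_k=k, ppm_error=float(err))
    return out


def annotate_adducts_and_transformations(
    table: FeatureTable,
    parent_formula: ElementalFormula,
    prior: dict[str, Annotation] | None = None,
    parent_ion: IonSpecies = PROTONATED,
    adducts: list[IonSpecies] | None = None,
    transformations: list[TransformationRule] | None = None,
    ppm_tol: float = 5.0,
) -> dict[str, Annotation]:
    """Match unannotated features against the adduct and transformation
    catalogues.

    Candidates per feature: the parent ion itself, each adduct species
    applied to the parent's neutral mass, and each transformation applied to
    the parent ion's m/z. The best match by |ppm error| wins; a second match
    within 1 ppm of the best is reported in ``ambiguous_with``. Features
    with no candidate within ``ppm_tol`` stay unannotated (downstream:
    unknown).
    """
    prior = dict(prior or {})
    adducts = adducts if adducts is not None else chem.builtin_adducts()
    transformations = (transformations if transformations is not None
                       else chem.builtin_transformations())
    neutral = chem.monoisotopic_mass(parent_formula)
    parent_mz = chem.ion_mz(neutral, parent_ion)

    candidates: list[tuple[str, str, float]] = [("parent", parent_ion.name,
                                                 parent_mz)]
    candidates += [("adduct", sp.name, chem.ion_mz(neutral, sp))
                   for sp in adducts]
    candidates += [("transformation", r.name, parent_mz + r.mass_delta)
                   for r in transformations]

    out: dict[str, Annotation] = {}
    mzs = table.features["mz"]
    for fname in table.feature_names:
        if fname in prior:
            continue
        scored = []
        for kind, label, cmz in candidates:
            err = (mzs[fname] - cmz) / cmz * 1e6
            if abs(err) <= ppm_tol:
                scored.append((abs(err), kind, label, err))
        if not scored:
            continue
        scored.sort(key=lambda t: (t[0], t[2]))
        best = scored[0]
        ambiguous = tuple(s[2] for s in scored[1:] if s[0] - best[0] <= 1.0)
        out[fname] = Annotation(
            fname,
            {"parent": "parent", "adduct": "adduct",
             "transformation": "transformation"}[best[1]],
            rule=best[2], ppm_error=float(best[3]),
            ambiguous_with=ambiguous)
    return out


def classify_origin(has_shift_match: bool, coelutes_with_parent: bool,
                    in_enzyme_blank: bool | None,
                    in_substrate_blank: bool | None,
                    dose_responsive: bool) -> str:
    """Origin ladder for a transformation-matched (or unknown) feature.

    Evidence flags may be None when the corresponding blank runs are
    missing, in which case the origin is "undetermined" rather than
    guessed. Ties resolve in ladder order: artifact, impurity, contaminant,
    metabolite.
    """
    if has_shift_match and coelutes_with_parent:
        return "artifact"
    if in_enzyme_blank is None or in_substrate_blank is None:
        return "undetermined"
    if in_enzyme_blank and not in_substrate_blank:
        return "impurity"
    if in_substrate_blank:
        return "contaminant"
    if dose_responsive:
        return "metabolite" if has_shift_match else "unknown"
    return "unknown"


def annotate_isomers(annotations: dict[str, Annotation],
                     table: FeatureTable,
                     rt_tol_s: float = 10.0) -> dict[str, Annotation]:
    """Cross-link features matching the same rule at distinct RTs.

    Within each (class, rule) stratum, features more than ``rt_tol_s`` apart
    are isomers of one another, numbered 1..n by ascending retention time.
    Covers positional isomers, diastereomers, and parent conformers alike.
    """
    rt = table.features["rt"]
    by_rule: dict[tuple[str, str], list[str]] = {}
    for f, ann in annotations.items():
        if ann.class_label in ("metabolite", "artifact", "parent", "impurity",
                               "contaminant") and (ann.rule or
                                                   ann.class_label == "parent"):
            key = (ann.class_label, ann.rule or "parent")
            by_rule.setdefault(key, []).append(f)
    for key, members in by_rule.items():
        if len(members) < 2:
            continue
        members = sorted(members, key=lambda f: rt[f])
        spread = rt[members[-1]] - rt[members[0]]
        if spread <= rt_tol_s:
            continue
        for i, f in enumerate(members, start=1):
            annotations[f].isomer_index = i
            annotations[f].isomer_of = tuple(m for m in members if m != f)
    return annotations


def _blank_presence(table: FeatureTable, sample_type: str,
                    threshold: float) -> pd.Series | None:
    ids = table.type_columns(sample_type)
    if not ids:
        return None
    return table.abundance[ids].mean(axis=1) > threshold


def annotate_features(
    table: FeatureTable,
    parent_formula: ElementalFormula,
    *,
    parent_ion: IonSpecies = PROTONATED,
    dose_responsive: set[str] | None = None,
    noise_floor: float = 0.0,
    blank_presence_factor: float = 3.0,
    ppm_tol: float = 5.0,
    rt_tol_s: float = 5.0,
    isomer_rt_tol_s: float = 10.0,
) -> dict[str, Annotation]:
    """Full annotation of a (significant) feature table with raw abundances.

    ``dose_responsive`` names features passing the significance filter with
    a positive Blank-to-High fold change. Presence in a blank means mean
    abundance above ``blank_presence_factor`` x ``noise_floor`` there.
    """
    dose_responsive = dose_responsive or set()
    ann = annotate_isotopes(table, rt_tol_s=rt_tol_s, ppm_tol=ppm_tol)
    matches = annotate_adducts_and_transformations(
        table, parent_formula, prior=ann, parent_ion=parent_ion,
        ppm_tol=ppm_tol)

    threshold = blank_presence_factor * noise_floor
    in_eb = _blank_presence(table, "enzyme_blank", threshold)
    in_sb = _blank_presence(table, "substrate_blank", threshold)
    rt = table.features["rt"]

    parent_feature = None
    parent_members = [f for f, a in matches.items()
                      if a.class_label == "parent"]
    if parent_members:
        mean_ab = table.abundance.mean(axis=1)
        parent_feature = max(parent_members, key=lambda f: mean_ab[f])

    out: dict[str, Annotation] = dict(ann)
    for fname in table.feature_names:
        if fname in out:
            continue
        a = matches.get(fname)
        coel = (parent_feature is not None
                and abs(rt[fname] - rt[parent_feature]) <= rt_tol_s)
        eb = None if in_eb is None else bool(in_eb[fname])
        sb = None if in_sb is None else bool(in_sb[fname])
        dr = fname in dose_responsive
        if a is None:
            out[fname] = Annotation(fname, "unknown",
                                    evidence={"in_enzyme_blank": eb,
                                              "in_substrate_blank": sb,
                                              "dose_responsive": dr})
            continue
        a.evidence = {"coelutes_with_parent": coel, "in_enzyme_blank": eb,
                      "in_substrate_blank": sb, "dose_responsive": dr}
        if a.class_label == "parent":
            a.parent_feature = parent_feature
            out[fname] = a
        elif a.class_label == "adduct":
            a.parent_feature = parent_feature
            out[fname] = a
        else:  # transformation match -> origin ladder
            origin = classify_origin(True, coel, eb, sb, dr)
            a.class_label = origin
            a.parent_feature = parent_feature
            out[fname] = a
    annotate_isomers(out, table, rt_tol_s=isomer_rt_tol_s)
    return out


def annotation_table(annotations: dict[str, Annotation],
                     table: FeatureTable,
                     polarity: str = "pos") -> pd.DataFrame:
    """Report table with columns mirroring a published significant-feature
    list: polarity, feature, measured m/z, retention time (s), identity."""
    rows = []
    for fname in table.feature_names:
        a = annotations.get(fname)
        rows.append({
            "polarity": polarity,
            "feature": fname,
            "mz": round(float(table.features.loc[fname, "mz"]), 4),
            "rt_s": int(round(float(table.features.loc[fname, "rt"]))),
            "identity": a.identity if a else "unknown",
            "class": a.class_label if a else "unknown",
            "rule": (a.rule or "") if a else "",
            "parent_feature": (a.parent_feature or "") if a else "",
            "ppm_error": (round(a.ppm_error, 2)
                          if a and np.isfinite(a.ppm_error) else ""),
        })
    df = pd.DataFrame(rows)
    return df.sort_values(["mz", "rt_s"]).reset_index(drop=True)
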