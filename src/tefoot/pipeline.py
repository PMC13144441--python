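"""End-to-end driver: intact copies -> profiles -> footprints -> motifs -> candidates.

Chains the whole footprint-to-candidate procedure on a simulated (or loaded)
dataset: select intact copies, build per-stage meta-profiles, call and unify
footprints, extract their consensus sequences, match them against the motif
library, and filter the matched TFs by embryonic expression.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .candidates import CandidateSet, expression_filter, merge_candidates
from .footprints import Footprint, FootprintCallParams, extract_footprint_sequence, unify_and_classify
from .motifs import scan_footprints
from .profiles import MetaProfile, build_meta_profile
from .repeats import IntactSet, select_intact
from .simulate import SimulatedDataset

__all__ = ["PipelineResult", "recover_tfs"]


@dataclass
class PipelineResult:
    """All intermediate and final products of one pipeline run."""

    intact: IntactSet
    profiles: dict[str, dict[str, MetaProfile]]      # family -> stage -> profile
    footprints: dict[str, list[Footprint]]           # family -> unified footprints
    matches: pd.DataFrame                            # all retained motif matches
    retained_tfs: list[str]                          # after the expression filter
    candidates: CandidateSet


def recover_tfs(
    ds: SimulatedDataset,
    params: FootprintCallParams | None = None,
    e_threshold: float = 30.0,
    n_perm: int = 999,
    seed: int = 0,
    pad: int = 3,
    min_reads: int = 2,
) -> PipelineResult:
    """Run the full candidate-discovery pipeline on a dataset.

    ``pad`` extends each footprint interval before sequence extraction so a
    motif straddling the called boundary is still alignable.
    """
    params = params or FootprintCallParams()
    library = ds.consensus_library
    intact = select_intact(ds.copies, library, tolerance_bp=0)
    profiles: dict[str, dict[str, MetaProfile]] = {}
    footprints: dict[str, list[Footprint]] = {}
    seqs: dict[str, tuple[str, str]] = {}
    fp_family: dict[str, str] = {}
    for family in sorted(intact.families()):
        profiles[family] = {
            stage: build_meta_profile(track, intact, family)
            for stage, track in ds.tracks.items()
        }
        footprints[family] = unify_and_classify(profiles[family], params)
        for fp in footprints[family]:
            seqs[fp.name] = extract_footprint_sequence(fp, library, pad=pad)
            fp_family[fp.name] = family
    matches = scan_footprints(
        seqs, ds.motif_library, ds.truth.tf_map,
        e_threshold=e_threshold, n_perm=n_perm, seed=seed,
    )
    matched_tfs = sorted(matches["tf"].unique()) if len(matches) else []
    retained = expression_filter(ds.expression, matched_tfs, min_reads=min_reads)
    retained_set = set(retained)
    by_family: dict[str, pd.DataFrame] = {}
    for family in profiles:
        if len(matches):
            fam_mask = matches["footprint"].map(fp_family) == family
            by_family[family] = matches[fam_mask & matches["tf"].isin(retained_set)]
        else:
            by_family[family] = matches
    candidates = merge_candidates(by_family)
    return PipelineResult(
        intact=intact,
        profiles=profiles,
        footprints=footprints,
        matches=matches,
        retained_tfs=retained,
        candidates=candidates,
    )
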