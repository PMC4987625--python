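"""Reading and writing the pipeline's tabular and sequence formats."""

from __future__ import annotations

import gzip
import json

import pandas as pd
from Bio import SeqIO

from .antigen import FUSION, ReferenceAntigen, ResidueSpan
from .enrichment import LibraryCounts, ResidueEnrichmentProfile
from .frames import MappedFragment
from .hotspots import HotspotCall


def iter_reads(path: str):
    """Yield ``(read_id, sequence)`` from FASTA/FASTQ, optionally gzipped."""
    fmt = "fastq" if ".fastq" in path or ".fq" in path else "fasta"
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq)


def write_classification_tsv(fragments: list[MappedFragment], path: str) -> None:
    rows = []
    for f in fragments:
        rows.append({
            "read_id": f.read_id,
            "class": f.frame_class,
            "orientation": f.orientation or ".",
            "nt_start": f.span_nt[0] if f.span_nt else ".",
            "nt_end": f.span_nt[1] if f.span_nt else ".",
            "res_start": f.span_res.start_res if f.span_res else ".",
            "res_end": f.span_res.end_res if f.span_res else ".",
            "frame5": f.frame5 if f.frame5 is not None else ".",
            "len_mod3": f.len_mod3 if f.len_mod3 is not None else ".",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_classification_tsv(path: str) -> list[MappedFragment]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fragments = []
    for row in df.to_dict("records"):
        span_nt = None
        span_res = None
        if row["nt_start"] != ".":
            span_nt = (int(row["nt_start"]), int(row["nt_end"]))
        if row["res_start"] != ".":
            span_res = ResidueSpan(int(row["res_start"]), int(row["res_end"]),
                                   FUSION)
        fragments.append(MappedFragment(
            read_id=row["read_id"],
            frame_class=row["class"],
            orientation=None if row["orientation"] == "." else row["orientation"],
            span_nt=span_nt,
            span_res=span_res,
            frame5=None if row["frame5"] == "." else int(row["frame5"]),
            len_mod3=None if row["len_mod3"] == "." else int(row["len_mod3"]),
        ))
    return fragments


def library_counts_from_tsv(path: str, library_id: str) -> LibraryCounts:
    return LibraryCounts.from_fragments(read_classification_tsv(path), library_id)


def write_profile_tsv(
    profile: ResidueEnrichmentProfile, path: str
) -> None:
    df = pd.DataFrame({
        "residue": range(1, len(profile) + 1),
        "occ_unselected": profile.occurrence_unselected,
        "occ_selected": profile.occurrence_selected,
        "enrichment_factor": profile.enrichment_factor,
    })
    if profile.counts_unselected is not None:
        df["count_unselected"] = profile.counts_unselected
        df["count_selected"] = profile.counts_selected
    df.to_csv(path, sep="\t", index=False)
    meta = {"pseudocount": profile.pseudocount,
            "n_unselected": profile.n_unselected,
            "n_selected": profile.n_selected}
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh)


def read_profile_tsv(path: str) -> ResidueEnrichmentProfile:
    df = pd.read_csv(path, sep="\t")
    meta = {"pseudocount": 1.0, "n_unselected": None, "n_selected": None}
    try:
        with open(path + ".json") as fh:
            meta.update(json.load(fh))
    except FileNotFoundError:
        pass
    return ResidueEnrichmentProfile(
        occurrence_unselected=df["occ_unselected"].to_numpy(),
        occurrence_selected=df["occ_selected"].to_numpy(),
        enrichment_factor=df["enrichment_factor"].to_numpy(),
        pseudocount=meta["pseudocount"],
        counts_unselected=(df["count_unselected"].to_numpy()
                           if "count_unselected" in df else None),
        counts_selected=(df["count_selected"].to_numpy()
                         if "count_selected" in df else None),
        n_unselected=meta["n_unselected"],
        n_selected=meta["n_selected"],
    )


def write_hotspots_tsv(
    calls: list[HotspotCall],
    regions: list[ResidueSpan],
    path: str,
) -> None:
    rows = []
    for call, region in zip(calls, regions):
        rows.append({
            "boundary": call.boundary,
            "direction": call.direction,
            "jump_score": call.jump_score,
            "candidate_start": region.start_res,
            "candidate_end": region.end_res,
        })
    pd.DataFrame(
        rows, columns=["boundary", "direction", "jump_score",
                       "candidate_start", "candidate_end"]
    ).to_csv(path, sep="\t", index=False)


def write_ranked_fragments_tsv(calls, path: str, ref: ReferenceAntigen | None = None) -> None:
    rows = []
    for rank, c in enumerate(calls, start=1):
        rows.append({
            "rank": rank,
            "res_start": c.span.start_res,
            "res_end": c.span.end_res,
            "label": c.span.label(ref.protein if ref else None),
            "frequency_selected": c.frequency_selected,
            "frequency_unselected": c.frequency_unselected,
            "significant": c.significant,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
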