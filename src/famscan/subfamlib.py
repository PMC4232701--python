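"""Fragment regions, subclade-restricted HMM libraries, tail truncation.

Draft assemblies rarely contain full-length genes, so profiles are built
from short fragment regions of a reference alignment (named after the
transmembrane-domain landmarks they span in the GPCR-like family the
package targets, e.g. TM1-4).  A library holds one calibrated profile per
(subfamily, region) pair, built from only the training sequences carrying
that subfamily's label, plus optional decoy profiles from unrelated
families used by reciprocal validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

from . import profilehmm
from .profilehmm import ProfileHMM, build_profile, calibrate
from .seqkit import MsAlignment

DEFAULT_REGION_NAMES = ("TM1-4", "TM4-5", "TM6", "TM6-7")


@dataclass(frozen=True)
class FragmentRegion:
    """A named half-open column interval [start_col, end_col) on a reference alignment."""

    name: str
    start_col: int
    end_col: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_col < self.end_col:
            raise ValueError(f"region {self.name!r}: invalid interval "
                             f"[{self.start_col}, {self.end_col})")

    @property
    def ncols(self) -> int:
        return self.end_col - self.start_col


@dataclass
class HmmLibrary:
    """Calibrated profiles keyed by (subfamily, region), plus decoys."""

    profiles: dict[tuple[str, str], ProfileHMM] = field(default_factory=dict)
    decoys: list[ProfileHMM] = field(default_factory=list)
    regions: list[FragmentRegion] = field(default_factory=list)
    missing: list[tuple[str, str]] = field(default_factory=list)
    reference_alignment: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def subfamilies(self) -> list[str]:
        return sorted({sf for sf, _ in self.profiles})

    @property
    def region_names(self) -> list[str]:
        return [r.name for r in self.regions]

    def all_profiles(self, include_decoys: bool = True) -> list[ProfileHMM]:
        out = list(self.profiles.values())
        if include_decoys:
            out.extend(self.decoys)
        return out


def trim_to_region(aln: MsAlignment, region: FragmentRegion,
                   min_residues: int | None = None) -> MsAlignment:
    """Cut an alignment down to one fragment region, dropping sparse rows.

    Rows with fewer than min_residues non-gap characters inside the region
    (default: half the region's columns) are excluded, mirroring a
    full-length-sequences-only training policy.
    """
    if region.end_col > aln.ncols:
        raise ValueError(f"region {region.name!r} exceeds alignment width "
                         f"({region.end_col} > {aln.ncols})")
    if min_residues is None:
        min_residues = max(1, region.ncols // 2)
    rows = []
    for name, seq in aln.rows:
        sub = seq[region.start_col:region.end_col]
        if sum(1 for c in sub if c != "-") >= min_residues:
            rows.append((name, sub))
    if not rows:
        raise ValueError(f"region {region.name!r}: all rows dropped "
                         f"(min_residues={min_residues})")
    keep = {name for name, _ in rows}
    return MsAlignment(rows, {n: l for n, l in aln.labels.items() if n in keep})


def build_library(aln: MsAlignment, regions: list[FragmentRegion], *,
                  symfrac: float = profilehmm.DEFAULT_SYMFRAC,
                  tau: float = profilehmm.DEFAULT_TAU,
                  weighting: str = "position",
                  min_residues: int | None = None,
                  n_cal: int = profilehmm.DEFAULT_N_CAL,
                  seed: int = 0,
                  decoy_alignments: dict[str, MsAlignment] | None = None,
                  reference_alignment: str = "") -> HmmLibrary:
    """Build one calibrated profile per (subfamily, region).

    Training rows for each profile are restricted to sequences carrying
    that subfamily's label.  A (subfamily, region) pair whose trimmed
    sub-alignment is empty is recorded as missing (with a warning) rather
    than failing the whole build.  Decoy alignments, if given, yield one
    full-width calibrated profile each.
    """
    subfams = sorted(set(aln.labels.values()))
    if len(subfams) < 2:
        raise ValueError("need >= 2 subfamily labels to build a library")
    names = {name for r in regions for name in [r.name]}
    if len(names) != len(regions):
        raise ValueError("region names must be unique")
    lib = HmmLibrary(regions=list(regions), reference_alignment=reference_alignment)
    training_rows: dict[str, list[str]] = {}
    cal_seed = seed
    for sf in subfams:
        ids = [n for n in aln.ids if aln.labels.get(n) == sf]
        sub = aln.subset(ids)
        for region in regions:
            cal_seed += 1
            try:
                trimmed = trim_to_region(sub, region, min_residues)
                training_rows[f"{sf}|{region.name}"] = trimmed.ids
                hmm = build_profile(trimmed, name=f"{sf}:{region.name}",
                                    subfamily=sf, region=region.name,
                                    symfrac=symfrac, tau=tau, weighting=weighting)
            except ValueError as exc:
                warnings.warn(f"missing profile for ({sf}, {region.name}): {exc}")
                lib.missing.append((sf, region.name))
                continue
            calibrate(hmm, n_cal=n_cal, seed=cal_seed)
            lib.profiles[(sf, region.name)] = hmm
    for decoy_name, decoy_aln in (decoy_alignments or {}).items():
        cal_seed += 1
        hmm = build_profile(decoy_aln, name=f"decoy:{decoy_name}",
                            subfamily=f"decoy:{decoy_name}", region="full",
                            symfrac=symfrac, tau=tau, weighting=weighting)
        calibrate(hmm, n_cal=n_cal, seed=cal_seed)
        lib.decoys.append(hmm)
    lib.provenance = {
        "training_rows": training_rows,
        "training_ids": aln.ids,
        "subfamilies": subfams,
        "regions": [(r.name, r.start_col, r.end_col) for r in regions],
        "symfrac": symfrac, "tau": tau, "weighting": weighting,
        "min_residues": min_residues, "n_cal": n_cal, "seed": seed,
    }
    return lib


def truncate_at_landmark(seqs: list[tuple[str, str]], aln: MsAlignment,
                         landmark_col: int) -> list[tuple[str, str]]:
    """Cut each sequence after its residue aligned at landmark_col.

    The alignment supplies the coordinate mapping: a row's cut point is the
    number of its residues in columns [0, landmark_col].  Sequences whose
    row is entirely gapped after the landmark are returned unchanged, as
    are sequences without an alignment row.  Used as the tail-loss control:
    deleting everything beyond a C-terminal landmark from tailed training
    sequences must not change classifications of naturally tail-less genes.
    """
    if not 0 <= landmark_col < aln.ncols:
        raise ValueError(f"landmark column {landmark_col} out of range")
    aligned = dict(aln.rows)
    out = []
    for name, seq in seqs:
        row = aligned.get(name)
        if row is None:
            out.append((name, seq))
            continue
        n_before = sum(1 for c in row[:landmark_col + 1] if c != "-")
        n_after = sum(1 for c in row[landmark_col + 1:] if c != "-")
        if n_after == 0 or n_before == 0:
            out.append((name, seq))
        else:
            out.append((name, seq[:n_before]))
    return out


def truncate_alignment_at_landmark(aln: MsAlignment, landmark_col: int,
                                   subfamilies: set[str] | None = None) -> MsAlignment:
    """Gap out all columns after the landmark for the selected subfamilies."""
    rows = []
    pad = "-" * (aln.ncols - landmark_col - 1)
    for name, seq in aln.rows:
        if subfamilies is None or aln.labels.get(name) in subfamilies:
            rows.append((name, seq[:landmark_col + 1] + pad))
        else:
            rows.append((name, seq))
    return MsAlignment(rows, dict(aln.labels))


def save_library(lib: HmmLibrary, path: str) -> None:
    doc = {
        "schema": "famscan-hmmlib-1",
        "reference_alignment": lib.reference_alignment,
        "regions": [(r.name, r.start_col, r.end_col) for r in lib.regions],
        "missing": lib.missing,
        "provenance": lib.provenance,
        "profiles": [profilehmm.to_dict(h) for h in lib.profiles.values()],
        "decoys": [profilehmm.to_dict(h) for h in lib.decoys],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_library(path: str) -> HmmLibrary:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != "famscan-hmmlib-1":
        raise ValueError(f"unsupported library schema: {doc.get('schema')!r}")
    lib = HmmLibrary(
        regions=[FragmentRegion(*r) for r in doc["regions"]],
        missing=[tuple(m) for m in doc["missing"]],
        reference_alignment=doc.get("reference_alignment", ""),
        provenance=doc.get("provenance", {}),
    )
    for d in doc["profiles"]:
        hmm = profilehmm.from_dict(d)
        lib.profiles[(hmm.subfamily, hmm.region)] = hmm
    lib.decoys = [profilehmm.from_dict(d) for d in doc["decoys"]]
    return lib
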