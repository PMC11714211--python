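"""Drug-library screening: run the three network statistics and intersect.

Each drug in the target library is screened by closest proximity (NP),
GO functional similarity (FS, when an ontology is supplied) and RWR
diffusion correlation, each with its permutation null, and the printed
candidate rules are applied:

    NP:  Z_NP < -3  and P < 0.05
    FS:  FS > 0.6   and P < 0.05
    RWR: Z_RWR > 3  and P < 0.05

A final candidate must pass all three.  Per-drug permutation seeds are
derived deterministically from (master seed, drug id, method), so the
whole screen is reproducible bit-for-bit and adding or removing drugs does
not perturb the nulls of the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TextIO

import numpy as np
import pandas as pd

from netscreen.diffusion import (
    RwrConfig,
    RwrResult,
    Z_RWR_THRESHOLD,
    module_vector,
    rwr_screen,
)
from netscreen.funcsim import (
    AnnotationMap,
    FS_THRESHOLD,
    FsResult,
    GoDag,
    fs_screen,
)
from netscreen.interactome import GeneSet, InteractomeGraph
from netscreen.propagation import GeneModule
from netscreen.proximity import Z_NP_THRESHOLD, ProximityResult, proximity_screen

__all__ = [
    "DrugTargetLibrary",
    "ScreenConfig",
    "DrugScreenRow",
    "ScreenReport",
    "load_drug_library",
    "write_drug_library",
    "run_screen",
    "derive_seed",
]

P_THRESHOLD = 0.05


def derive_seed(master_seed: int, *parts: str) -> int:
    """Deterministic child seed from a master seed and string labels.

    Hash-based (SHA-256), stable across processes, always below 2**31.
    """
    payload = "|".join([str(master_seed), *parts]).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class DrugTargetLibrary:
    """Drug id -> target gene set, with provenance of the affinity filter."""

    targets: dict[str, GeneSet]
    affinity_filtered: bool = False
    affinity_threshold: float | None = None
    n_dropped_affinity: int = 0

    def __len__(self) -> int:
        return len(self.targets)

    def __iter__(self):
        return iter(sorted(self.targets))

    def __getitem__(self, drug_id: str) -> GeneSet:
        return self.targets[drug_id]


def load_drug_library(
    source: str | Path | TextIO,
    affinity_threshold: float = 10.0,
    header: bool = False,
) -> DrugTargetLibrary:
    """Read a drug->target TSV: ``drug<TAB>target[<TAB>affinity]``.

    When the affinity column is present, rows above the threshold
    (default 10, the conventional binding-affinity cutoff in uM) are
    dropped and counted; without the column all rows are kept.  Duplicate
    (drug, target) rows collapse.  Raises on an empty library.
    """
    close = isinstance(source, (str, Path))
    stream = open(source) if close else source
    try:
        targets: dict[str, set[str]] = {}
        n_dropped = 0
        saw_affinity = False
        n_rows = 0
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if header:
                header = False
                continue
            cols = line.split("\t")
            if len(cols) < 2 or not cols[0].strip() or not cols[1].strip():
                raise ValueError(f"malformed drug-target row at line {lineno}: {line!r}")
            drug, gene = cols[0].strip(), cols[1].strip()
            n_rows += 1
            if len(cols) >= 3 and cols[2].strip():
                saw_affinity = True
                if float(cols[2]) > affinity_threshold:
                    n_dropped += 1
                    continue
            targets.setdefault(drug, set()).add(gene)
        if n_rows == 0:
            raise ValueError("empty drug-target library")
        return DrugTargetLibrary(
            targets={d: GeneSet(d, g) for d, g in targets.items() if g},
            affinity_filtered=saw_affinity,
            affinity_threshold=affinity_threshold if saw_affinity else None,
            n_dropped_affinity=n_dropped,
        )
    finally:
        if close:
            stream.close()


def write_drug_library(library: DrugTargetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for drug in library:
            for gene in sorted(library[drug].members):
                fh.write(f"{drug}\t{gene}\n")


@dataclass
class ScreenConfig:
    """Knobs of the full screen; defaults follow the screening conventions
    documented in each method module."""

    n_perm: int = 1000
    master_seed: int = 0
    min_bin_size: int = 100
    np_randomize: str = "both"          # randomize both sets in the NP null
    np_p_tail: str = "less"             # printed counting rule #{d_random < d}
    fs_null: str = "annotated"
    rwr: RwrConfig = field(default_factory=RwrConfig)
    rwr_seed_mode: str = "module"       # module-side RWR seeds: "module" | "seed_gene"


@dataclass
class DrugScreenRow:
    """All per-drug evidence collected by the screen."""

    drug_id: str
    proximity: ProximityResult | None = None
    funcsim: FsResult | None = None
    rwr: RwrResult | None = None
    skip_reasons: dict[str, str] = field(default_factory=dict)

    @property
    def pass_np(self) -> bool:
        return self.proximity is not None and self.proximity.passes

    @property
    def pass_fs(self) -> bool:
        return self.funcsim is not None and self.funcsim.passes

    @property
    def pass_rwr(self) -> bool:
        return self.rwr is not None and self.rwr.passes

    @property
    def final_candidate(self) -> bool:
        return self.pass_np and self.pass_fs and self.pass_rwr


@dataclass
class ScreenReport:
    """Screen outcome over the whole library.

    Besides the three-way intersection (the candidate rule), every pairwise
    intersection is exposed -- promoting drugs that pass only two methods is
    a judgment call left to the user.
    """

    rows: dict[str, DrugScreenRow]
    config: ScreenConfig
    module_members: list[str]
    fs_available: bool

    def candidates(self, method: str) -> list[str]:
        flag = {"np": "pass_np", "fs": "pass_fs", "rwr": "pass_rwr"}[method]
        return sorted(d for d, r in self.rows.items() if getattr(r, flag))

    @property
    def final_candidates(self) -> list[str]:
        return sorted(d for d, r in self.rows.items() if r.final_candidate)

    def pairwise_intersections(self) -> dict[str, list[str]]:
        np_c, fs_c, rwr_c = (
            set(self.candidates("np")),
            set(self.candidates("fs")),
            set(self.candidates("rwr")),
        )
        return {
            "np_fs": sorted(np_c & fs_c),
            "np_rwr": sorted(np_c & rwr_c),
            "fs_rwr": sorted(fs_c & rwr_c),
            "np_fs_rwr": sorted(np_c & fs_c & rwr_c),
        }

    def apply_thresholds(
        self,
        z_np: float = Z_NP_THRESHOLD,
        fs: float = FS_THRESHOLD,
        z_rwr: float = Z_RWR_THRESHOLD,
        p: float = P_THRESHOLD,
    ) -> list[str]:
        """Re-derive the final candidate list under alternative cutoffs.

        Loosening any threshold can only grow the list (monotonicity).
        """
        out = []
        for drug, row in sorted(self.rows.items()):
            if row.proximity is None or row.rwr is None or row.funcsim is None:
                continue
            ok = (
                not np.isnan(row.proximity.z_np)
                and row.proximity.z_np < z_np
                and row.proximity.p < p
                and row.funcsim.fs > fs
                and row.funcsim.p < p
                and not np.isnan(row.rwr.z_rwr)
                and row.rwr.z_rwr > z_rwr
                and row.rwr.p < p
            )
            if ok:
                out.append(drug)
        return out

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        records = []
        for drug, row in sorted(self.rows.items()):
            rec: dict[str, object] = {"drug": drug}
            if row.proximity is not None:
                rec.update(
                    d_np=row.proximity.d_obs,
                    z_np=row.proximity.z_np,
                    p_np=row.proximity.p,
                    n_targets=row.proximity.n_targets_in_graph,
                )
            if row.funcsim is not None:
                rec.update(fs=row.funcsim.fs, p_fs=row.funcsim.p)
            if row.rwr is not None:
                rec.update(cor_rwr=row.rwr.cor_obs, z_rwr=row.rwr.z_rwr, p_rwr=row.rwr.p)
            rec.update(
                pass_np=row.pass_np,
                pass_fs=row.pass_fs,
                pass_rwr=row.pass_rwr,
                final_candidate=row.final_candidate,
                skip_reasons=";".join(
                    f"{m}:{r}" for m, r in sorted(row.skip_reasons.items())
                ),
            )
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def write(self, out_dir: str | Path) -> None:
        """Write per-method TSVs, the combined report, and a run manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame = self.to_frame()
        kw = dict(sep="\t", index=False, float_format="%.10g", lineterminator="\n")
        frame.to_csv(out / "report.tsv", **kw)
        cols = {
            "proximity": ["drug", "d_np", "z_np", "p_np", "n_targets", "pass_np"],
            "funcsim": ["drug", "fs", "p_fs", "pass_fs"],
            "rwr": ["drug", "cor_rwr", "z_rwr", "p_rwr", "pass_rwr"],
        }
        for name, cc in cols.items():
            sub = frame[[c for c in cc if c in frame.columns]]
            sub.to_csv(out / f"{name}.tsv", **kw)
        manifest = {
            "n_drugs": len(self.rows),
            "n_perm": self.config.n_perm,
            "master_seed": self.config.master_seed,
            "min_bin_size": self.config.min_bin_size,
            "np_randomize": self.config.np_randomize,
            "np_p_tail": self.config.np_p_tail,
            "fs_null": self.config.fs_null,
            "rwr_gamma": self.config.rwr.gamma,
            "rwr_seed_mode": self.config.rwr_seed_mode,
            "fs_available": self.fs_available,
            "module_size": len(self.module_members),
            "candidates": {
                "np": self.candidates("np"),
                "fs": self.candidates("fs"),
                "rwr": self.candidates("rwr"),
                "final": self.final_candidates,
            },
            "pairwise_intersections": self.pairwise_intersections(),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_screen(
    graph: InteractomeGraph,
    module: GeneModule,
    library: DrugTargetLibrary,
    dag: GoDag | None = None,
    annot: AnnotationMap | None = None,
    config: ScreenConfig | None = None,
) -> ScreenReport:
    """Screen every drug in the library with all three statistics.

    Per-drug failures (no mapped targets, no annotation overlap, zero
    variance) are recorded as skip reasons on that drug's row and never
    abort the screen.  FS is skipped wholesale, with a reason, when no
    ontology/annotation pair is supplied.
    """
    config = config or ScreenConfig()
    module_set = module.gene_set.restrict(graph.nodes)
    if not module_set.members:
        raise ValueError("module has no gene in the graph")
    if config.rwr_seed_mode == "module":
        rwr_seeds = module_set
    elif config.rwr_seed_mode == "seed_gene":
        rwr_seeds = GeneSet("seed", module.seed)
    else:
        raise ValueError(f"unknown rwr_seed_mode {config.rwr_seed_mode!r}")
    mod_vec = module_vector(graph, rwr_seeds, config.rwr)
    fs_available = dag is not None and annot is not None

    rows: dict[str, DrugScreenRow] = {}
    for drug in library:
        row = DrugScreenRow(drug_id=drug)
        targets = library[drug]
        in_graph = targets.restrict(graph.nodes)
        n_unmapped = len(targets) - len(in_graph)
        if n_unmapped:
            row.skip_reasons.setdefault(
                "targets", f"{n_unmapped} target(s) not in interactome"
            )
        if not in_graph.members:
            row.skip_reasons["np"] = "no target in interactome"
            row.skip_reasons["rwr"] = "no target in interactome"
        else:
            try:
                row.proximity = proximity_screen(
                    graph,
                    in_graph,
                    module_set,
                    n_perm=config.n_perm,
                    rng_seed=derive_seed(config.master_seed, drug, "np"),
                    min_bin_size=config.min_bin_size,
                    randomize=config.np_randomize,
                    p_tail=config.np_p_tail,
                    drug_id=drug,
                )
            except ValueError as exc:
                row.skip_reasons["np"] = str(exc)
            try:
                row.rwr = rwr_screen(
                    graph,
                    in_graph,
                    mod_vec,
                    n_perm=config.n_perm,
                    rng_seed=derive_seed(config.master_seed, drug, "rwr"),
                    config=config.rwr,
                    min_bin_size=config.min_bin_size,
                    drug_id=drug,
                )
            except ValueError as exc:
                row.skip_reasons["rwr"] = str(exc)
        if fs_available:
            try:
                row.funcsim = fs_screen(
                    dag,
                    annot,
                    targets,
                    module_set,
                    n_perm=config.n_perm,
                    rng_seed=derive_seed(config.master_seed, drug, "fs"),
                    null=config.fs_null,
                    graph=graph,
                    drug_id=drug,
                )
            except ValueError as exc:
                row.skip_reasons["fs"] = str(exc)
        else:
            row.skip_reasons["fs"] = "no ontology/annotations supplied"
        rows[drug] = row
    return ScreenReport(
        rows=rows,
        config=config,
        module_members=list(module.members),
        fs_available=fs_available,
    )
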