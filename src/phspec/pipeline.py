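"""End-to-end orchestration.

Runs profiles -> motif scan -> classification on sequence inputs, and
SASA / contact / electrostatics stages on any structure inputs, from a
single YAML configuration.  Every tabular output is TSV with a fixed
column order and a header comment naming the configuration hash that
produced it, so a run can be reproduced byte-for-byte from the copy of
the config that is serialized into its output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import AlignIO, SeqIO

from . import classifier as clf
from . import contacts as ct
from . import electrostatics as es
from . import motif as mt
from . import properties as props
from . import sasa as sa
from .structure import read_structure

DEFAULT_SCALES = ("H", "F", "E", "I")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: Path
    sequences: Path | None = None  # FASTA
    alignment: Path | None = None  # Stockholm or aligned FASTA
    pdbs: list[dict] = field(default_factory=list)  # {id, path, ligand_resname}
    scales: tuple[str, ...] = DEFAULT_SCALES
    window: int = 9
    loop_window: tuple[int, int] = (10, 28)
    loop_coordinates: str = "sequence"
    thresholds: dict | None = None
    motif_file: Path | None = None
    probe: float = 1.4
    slice_spacing: float = 0.1
    pb: dict = field(default_factory=dict)
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls(out_dir=Path(raw.get("out_dir", "phspec_out")))
        for key in ("sequences", "alignment", "motif_file"):
            if raw.get(key):
                setattr(cfg, key, Path(raw[key]))
        cfg.pdbs = list(raw.get("pdbs", []))
        cfg.scales = tuple(raw.get("scales", DEFAULT_SCALES))
        cfg.window = int(raw.get("window", 9))
        if cfg.window % 2 == 0 or not (1 <= cfg.window <= 21):
            raise ValueError("window must be odd, between 1 and 21")
        if "loop_window" in raw:
            lo, hi = raw["loop_window"]
            cfg.loop_window = (int(lo), int(hi))
        cfg.loop_coordinates = raw.get("loop_coordinates", "sequence")
        cfg.thresholds = raw.get("thresholds")
        cfg.probe = float(raw.get("probe", 1.4))
        cfg.slice_spacing = float(raw.get("slice_spacing", 0.1))
        cfg.pb = dict(raw.get("pb", {}))
        cfg.seed = int(raw.get("seed", 1))
        return cfg

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "sequences": str(self.sequences) if self.sequences else None,
            "alignment": str(self.alignment) if self.alignment else None,
            "pdbs": self.pdbs,
            "scales": list(self.scales),
            "window": self.window,
            "loop_window": list(self.loop_window),
            "loop_coordinates": self.loop_coordinates,
            "thresholds": self.thresholds,
            "motif_file": str(self.motif_file) if self.motif_file else None,
            "probe": self.probe,
            "slice_spacing": self.slice_spacing,
            "pb": self.pb,
            "seed": self.seed,
        }

    @property
    def config_hash(self) -> str:
        # out_dir is where results land, not a scientific input
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def load_ligand_descriptors() -> pd.DataFrame:
    """Packaged quantum-chemical ligand descriptor table (read-only)."""
    with resources.as_file(
        resources.files("phspec").joinpath("data", "ligand_descriptors.tsv")
    ) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_reference_groups() -> dict[str, int]:
    """Packaged reference group labels of representative PH domains."""
    text = resources.files("phspec").joinpath(
        "data", "reference_groups.tsv").read_text()
    out = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line or line.startswith("domain"):
            continue
        dom, grp = line.split()
        out[dom] = int(grp)
    return out


def _write_tsv(frame: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# phspec config={cfg_hash}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _read_alignment(path: Path) -> dict[str, str]:
    fmt = "stockholm" if path.suffix.lower() in (".sto", ".stk", ".stockholm") \
        else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return {rec.id: props.normalize_gaps(str(rec.seq).upper()) for rec in aln}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns a report bundle dict.

    Sequence stages run whenever sequences or an alignment are given;
    structure stages run per configured PDB entry and are skipped with
    a log notice otherwise.  Any stage failure halts the pipeline with
    the stage name, leaving earlier outputs in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    log: list[str] = [f"config hash {cfg_hash}"]
    bundle: dict = {"config_hash": cfg_hash, "outputs": {}}
    stage = "setup"
    try:
        # ---------------- sequences ---------------------------------
        stage = "sequences"
        seqs: dict[str, str] = {}
        alignment: dict[str, str] | None = None
        if config.alignment:
            alignment = _read_alignment(config.alignment)
            seqs = {k: v.replace("-", "") for k, v in alignment.items()}
        if config.sequences:
            for rec in SeqIO.parse(str(config.sequences), "fasta"):
                seqs[rec.id] = str(rec.seq).upper()
        if not seqs:
            raise ValueError("no sequences configured")
        log.append(f"loaded {len(seqs)} sequences"
                   + (" (aligned)" if alignment else ""))

        stage = "profiles"
        t0 = time.perf_counter()
        scales = {s: props.load_scale(s) for s in config.scales}
        profiles = {
            sid: {s: props.compute_profile(seq, scales[s], config.window,
                                           sequence_id=sid)
                  for s in config.scales}
            for sid, seq in seqs.items()
        }
        rows = []
        if alignment:
            aps = props.map_profiles_to_alignment(
                [p for by in profiles.values() for p in by.values()], alignment
            )
            for sid, row in aps.alignment.items():
                cmap = aps.column_maps[sid]
                for col, residx in enumerate(cmap):
                    rows.append({
                        "sequence_id": sid,
                        "alignment_column": col,
                        "residue_index": int(residx),
                        "residue": row[col],
                        **{s: aps.profiles[sid][s][col] for s in config.scales},
                    })
            if len(alignment) >= 2:
                bundle["average_pairwise_identity"] = \
                    props.average_pairwise_identity(alignment)
        else:
            for sid, seq in seqs.items():
                for i, aa in enumerate(seq):
                    rows.append({
                        "sequence_id": sid,
                        "alignment_column": i,
                        "residue_index": i,
                        "residue": aa,
                        **{s: profiles[sid][s].values[i] for s in config.scales},
                    })
        frame = pd.DataFrame(rows)
        _write_tsv(frame, out / "profiles.tsv", cfg_hash)
        bundle["outputs"]["profiles"] = out / "profiles.tsv"
        log.append(f"profiles: {len(frame)} rows "
                   f"({time.perf_counter() - t0:.2f}s)")

        # ---------------- motif + classification --------------------
        stage = "motif"
        patterns = (mt.load_patterns(config.motif_file) if config.motif_file
                    else mt.default_patterns())
        pattern = patterns[0]
        thresholds = (clf.ClassifierThresholds(**config.thresholds)
                      if config.thresholds else clf.default_thresholds())
        stage = "classify"
        predictions: dict[str, clf.GroupPrediction] = {}
        pred_rows = []
        for sid, seq in seqs.items():
            loops = clf.LoopAnnotation(
                windows={"beta1_beta2": config.loop_window},
                coordinate_system=config.loop_coordinates,
            )
            if loops.coordinate_system == "alignment":
                loops = loops.to_sequence(props.column_map(alignment[sid]))
            hits = mt.scan_motif(seq, pattern,
                                 loop_window=loops.windows["beta1_beta2"],
                                 sequence_id=sid)
            pred = clf.classify(
                {s: profiles[sid][s] for s in config.scales},
                hits, loops, thresholds,
            )
            predictions[sid] = pred
            pred_rows.append({
                "id": sid,
                "group": pred.group,
                "motif_hit": pred.motif_hit,
                "loop_H_max": pred.loop_hydropathy_max,
                "loop_E_max": pred.loop_charge_max,
                "loop_hydrophilicity": pred.loop_hydrophilicity,
                "rule_trace": json.dumps(pred.rule_trace),
            })
        _write_tsv(pd.DataFrame(pred_rows), out / "predictions.tsv", cfg_hash)
        bundle["outputs"]["predictions"] = out / "predictions.tsv"
        bundle["predictions"] = predictions

        reference = load_reference_groups()
        matched = set(predictions) & set(reference)
        if matched:
            ev = clf.evaluate_against_reference(predictions, reference)
            bundle["evaluation"] = ev
            log.append(f"reference comparison on {len(matched)} ids: "
                       f"accuracy {ev.accuracy:.3f}")
        else:
            log.append("reference comparison skipped: no matching identifiers")

        # ---------------- structures --------------------------------
        if not config.pdbs:
            log.append("structure stages skipped: no PDB inputs configured")
        sasa_rows, contact_frames = [], []
        for entry in config.pdbs:
            stage = f"structure:{entry.get('id', entry['path'])}"
            sid = entry.get("id", Path(entry["path"]).stem)
            structure = read_structure(Path(entry["path"]))
            ligand_resnames = entry.get("ligand_resname", "")
            ligand_resnames = ([r.strip() for r in ligand_resnames.split(",") if r]
                               if isinstance(ligand_resnames, str)
                               else list(ligand_resnames))
            protein = structure.protein()
            apo = sa.lee_richards_sasa(protein, config.probe,
                                       config.slice_spacing)
            expo = sa.exposure_fractions(apo, window=config.window)
            buried = None
            if ligand_resnames:
                lig = structure.ligand(ligand_resnames)
                if len(lig):
                    holo = sa.lee_richards_sasa(
                        _concat(protein, lig), config.probe,
                        config.slice_spacing)
                    buried = sa.delta_sasa(apo, holo)
                    contact_frames.append(
                        ct.analyze_complex(
                            _concat(protein, lig), ligand_resnames,
                            complex_id=sid, probe=config.probe,
                        ).to_frame()
                    )
            for i, key in enumerate(apo.residue_keys):
                sasa_rows.append({
                    "complex_id": sid,
                    "chain": key[0], "res_seq": key[1], "res_name": key[2],
                    "S0": apo.per_residue_area[i],
                    "S1": (apo.per_residue_area[i] - buried.buried[i]
                           if buried is not None else np.nan),
                    "exposure": expo.fractions[i],
                    "exposure_smoothed": expo.smoothed[i],
                    "binding_site": (bool(buried.binding_site[i])
                                     if buried is not None else False),
                })
            pb_cfg = config.pb
            if pb_cfg.get("enabled", False):
                stage = f"pb:{sid}"
                charges = es.assign_charges(protein)
                grid = es.build_grid(
                    protein,
                    padding=float(pb_cfg.get("padding", 20.0)),
                    n_longest=int(pb_cfg.get("n_longest", 123)),
                )
                es.solve_pb(
                    grid, protein, charges,
                    eps_solute=float(pb_cfg.get("eps_in", 2.0)),
                    eps_solvent=float(pb_cfg.get("eps_out", 80.0)),
                    ionic_strength=float(pb_cfg.get("salt", 0.145)),
                    mode=pb_cfg.get("mode", "nonlinear"),
                    tol=float(pb_cfg.get("tol", 1e-4)),
                )
                (out / f"{sid}_potential.dx").write_text(es.write_dx(grid))
                surf = es.surface_potential(protein, grid, probe=config.probe)
                _write_tsv(surf, out / f"{sid}_surface_potential.tsv", cfg_hash)
                bundle["outputs"][f"pb:{sid}"] = out / f"{sid}_potential.dx"
        if sasa_rows:
            _write_tsv(pd.DataFrame(sasa_rows), out / "sasa.tsv", cfg_hash)
            bundle["outputs"]["sasa"] = out / "sasa.tsv"
        if contact_frames:
            _write_tsv(pd.concat(contact_frames, ignore_index=True),
                       out / "contacts.tsv", cfg_hash)
            bundle["outputs"]["contacts"] = out / "contacts.tsv"
    except Exception as exc:
        log.append(f"FAILED at stage {stage}: {exc}")
        (out / "run.log").write_text("\n".join(log) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from exc
    (out / "run.log").write_text("\n".join(log) + "\n")
    bundle["log"] = log
    return bundle


def _concat(a, b):
    """Concatenate two structures (protein + ligand selections)."""
    from .structure import Structure

    return Structure(
        atom_names=a.atom_names + b.atom_names,
        elements=a.elements + b.elements,
        res_names=a.res_names + b.res_names,
        res_seq=np.concatenate([a.res_seq, b.res_seq]),
        chain_ids=a.chain_ids + b.chain_ids,
        coords=np.vstack([a.coords, b.coords]),
        radii=np.concatenate([a.radii, b.radii]),
        occupancies=np.concatenate([a.occupancies, b.occupancies]),
        is_hetero=np.concatenate([a.is_hetero, b.is_hetero]),
        model_id=a.model_id,
    )
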