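"""File formats: FASTA sequences, TSV datasets, JSON model archives.

FASTA parsing/writing delegates to Biopython; a pre-scan supplies the
line-numbered error for text appearing before the first header.  Model
archives are plain JSON — floats round-trip through ``repr`` so a loaded
model predicts bit-identically to the one saved.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.pipeline import Pipeline

from .descriptors import FEATURE_NAMES, PeptideFeaturizer, WindowParams
from .forest import CPPForest, DecisionTree, TreeNode
from .records import LabeledDataset, PeptideRecord, make_dataset, validate_sequence
from .scales import ScaleSet

ARCHIVE_VERSION = 1

PathLike = Union[str, Path]


class FastaError(ValueError):
    pass


def read_fasta(path: PathLike) -> List[PeptideRecord]:
    """Read a FASTA file into validated peptide records.

    The header token before the first whitespace becomes the record id;
    line-wrapped sequences are concatenated.  Sequence text before the
    first ``>`` header is a parse error reported with its line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                break
            raise FastaError(
                f"{path}: sequence before first header at line {lineno}")
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(validate_sequence(str(entry.seq), id=entry.id))
    return records


def write_fasta(records: List[PeptideRecord], path: PathLike) -> None:
    entries = [SeqRecord(Seq(r.sequence), id=r.id or "peptide", description="")
               for r in records]
    SeqIO.write(entries, str(path), "fasta")


def read_labeled_dataset(path: PathLike, dialect: str = "tsv",
                         negatives: Optional[PathLike] = None,
                         allow_duplicates: bool = False) -> LabeledDataset:
    """Load a training dataset.

    ``dialect="tsv"``: two-column text, ``sequence<TAB>label`` with label
    in {0, 1}.  ``dialect="fasta_pair"``: ``path`` holds the positives
    (label 1) and ``negatives`` the negatives (label 0).
    """
    if dialect == "tsv":
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}: expected 2 tab-separated columns at "
                        f"line {lineno}")
                seq, label_s = parts
                if label_s not in ("0", "1"):
                    raise ValueError(
                        f"{path}: label must be 0 or 1 at line {lineno}, "
                        f"got {label_s!r}")
                records.append(validate_sequence(
                    seq, id=f"row{lineno}", label=int(label_s)))
    elif dialect == "fasta_pair":
        if negatives is None:
            raise ValueError("fasta_pair dialect needs a negatives file")
        records = [r.with_label(1) for r in read_fasta(path)]
        records += [r.with_label(0) for r in read_fasta(negatives)]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return make_dataset(records, provenance=str(path),
                        allow_duplicates=allow_duplicates)


def write_labeled_dataset(dataset: LabeledDataset, path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in dataset.records:
            fh.write(f"{r.sequence}\t{r.label}\n")


def _scales_to_dict(s: ScaleSet) -> dict:
    return {"name": s.name, "hydrophobicity": s.hydrophobicity, "pka": s.pka,
            "logp_octanol": s.logp_octanol,
            "helix_propensity": s.helix_propensity,
            "pka_nterm": s.pka_nterm, "pka_cterm": s.pka_cterm}


def _scales_from_dict(d: dict) -> ScaleSet:
    return ScaleSet(**d)


def save_model(model: Pipeline, path: PathLike,
               seed: Optional[int] = None) -> None:
    """Serialize a fitted featurize+forest pipeline to a JSON archive."""
    feat: PeptideFeaturizer = model.named_steps["featurize"]
    forest: CPPForest = model.named_steps["forest"]
    archive = {
        "version": ARCHIVE_VERSION,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed if seed is not None else forest.random_state,
        "scale_set_name": feat.scales.name,
        "feature_order": forest.feature_order_,
        "featurizer": {
            "scales": _scales_to_dict(feat.scales),
            "window": {"width": feat.window.width, "step": feat.window.step,
                       "delta_angle": feat.window.delta_angle},
            "include_termini": feat.include_termini,
            "normalize_counts": feat.normalize_counts,
        },
        "forest": {
            "params": forest.get_params(),
            "oob_error": forest.oob_error_,
            "n_features_in": forest.n_features_in_,
            "trees": [
                {"root": t.root.to_dict(), "feature_subset": t.feature_subset,
                 "n_bootstrap": int(len(t.bootstrap_indices))}
                for t in forest.trees_
            ],
        },
    }
    with open(path, "w") as fh:
        json.dump(archive, fh)


def load_model(path: PathLike) -> Pipeline:
    """Load a model archive; prediction is bit-identical to the saved model."""
    path = Path(path)
    try:
        with open(path) as fh:
            archive = json.load(fh)
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: corrupt or truncated model archive: {e}")
    version = archive.get("version")
    if version != ARCHIVE_VERSION:
        raise ValueError(f"{path}: unsupported archive version {version!r}")
    if archive["feature_order"] != list(FEATURE_NAMES)[:len(archive["feature_order"])]:
        raise ValueError(f"{path}: feature_order does not match this build; "
                         "refusing to reorder silently")
    fz = archive["featurizer"]
    featurizer = PeptideFeaturizer(
        scales=_scales_from_dict(fz["scales"]),
        window=WindowParams(**fz["window"]),
        include_termini=fz["include_termini"],
        normalize_counts=fz["normalize_counts"],
    ).fit([])
    fo = archive["forest"]
    forest = CPPForest(**fo["params"])
    forest.trees_ = [
        DecisionTree(root=TreeNode.from_dict(t["root"]),
                     feature_subset=t["feature_subset"],
                     bootstrap_indices=np.arange(t["n_bootstrap"]))
        for t in fo["trees"]
    ]
    forest.oob_error_ = fo["oob_error"]
    forest.n_features_in_ = fo["n_features_in"]
    forest.classes_ = np.array([0, 1])
    forest.feature_order_ = archive["feature_order"]
    return Pipeline([("featurize", featurizer), ("forest", forest)])
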