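"""Readers and writers for the on-disk TSV/JSON formats.

Two similarity formats are supported: a full labeled matrix (first row and
first column are entity IDs) and a weighted edge list with columns
``id_a``, ``id_b``, ``weight`` which is symmetrized on read, unlisted
pairs defaulting to 0.  Associations are a two-column TSV of
(small-molecule ID, miRNA ID).  IDs are opaque, case-sensitive strings.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .graphlets import IsomerCatalog, enumerate_isomers
from .model import AssociationMatrix, ScoreMatrix, rank_predictions
from .similarity import SimilarityMatrix

logger = logging.getLogger("gismma")

EDGE_COLUMNS = ("id_a", "id_b", "weight")


def _warn_case_collisions(ids) -> None:
    lowered: dict[str, str] = {}
    for e in ids:
        other = lowered.setdefault(e.lower(), e)
        if other != e:
            logger.warning("ids differ only by case: %r vs %r", other, e)


def read_similarity(path, fmt: str = "matrix") -> SimilarityMatrix:
    """Read a similarity matrix from ``matrix`` or ``edges`` TSV format."""
    path = Path(path)
    if fmt == "matrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = tuple(str(c) for c in df.columns)
        row_ids = tuple(str(r) for r in df.index)
        if ids != row_ids:
            raise ValidationError(
                f"{path}: row ids do not match column ids"
            )
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric cell ({exc})") from None
        _warn_case_collisions(ids)
        return SimilarityMatrix(ids, values)
    if fmt == "edges":
        df = pd.read_csv(path, sep="\t")
        if tuple(df.columns[:3]) != EDGE_COLUMNS:
            # Tolerate headerless files with exactly three columns.
            df = pd.read_csv(path, sep="\t", header=None, names=EDGE_COLUMNS)
        ids = tuple(sorted(set(df["id_a"].astype(str)) | set(df["id_b"].astype(str))))
        pos = {e: k for k, e in enumerate(ids)}
        values = np.zeros((len(ids), len(ids)))
        np.fill_diagonal(values, 1.0)
        seen: dict[tuple[str, str], float] = {}
        for line, (a, b, w) in enumerate(
            zip(df["id_a"].astype(str), df["id_b"].astype(str), df["weight"]), start=2
        ):
            try:
                w = float(w)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}:{line}: non-numeric weight {w!r}"
                ) from None
            key = (min(a, b), max(a, b))
            if key in seen and seen[key] != w:
                raise ValidationError(
                    f"{path}:{line}: conflicting duplicate weight for "
                    f"{key[0]!r}-{key[1]!r}: {seen[key]!r} vs {w!r}"
                )
            seen[key] = w
            values[pos[a], pos[b]] = w
            values[pos[b], pos[a]] = w
        _warn_case_collisions(ids)
        return SimilarityMatrix(ids, values)
    raise ValidationError(f"unknown similarity format {fmt!r}")


def write_similarity(matrix: SimilarityMatrix, path) -> None:
    df = pd.DataFrame(
        matrix.values, index=list(matrix.entity_ids), columns=list(matrix.entity_ids)
    )
    df.to_csv(path, sep="\t")


def read_associations(
    path,
    sm_ids=None,
    mirna_ids=None,
) -> AssociationMatrix:
    """Read a two-column (sm_id, mirna_id) TSV into a binary adjacency.

    Without externally supplied id universes, the matrix is built over the
    sorted unique ids observed in the file.  Duplicate pairs collapse to a
    single association with a logged warning count.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValidationError(f"{path}:{line_no}: malformed line {line!r}")
            if line_no == 1 and fields[0].strip().lower() in ("sm_id", "sm", "small_molecule"):
                continue
            pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise ValidationError(f"{path}: no associations found")
    n_dupes = len(pairs) - len(set(pairs))
    if n_dupes:
        logger.warning("%s: %d duplicate association(s) collapsed", path, n_dupes)
    unique = sorted(set(pairs))
    sm_ids = tuple(sm_ids) if sm_ids is not None else tuple(sorted({s for s, _ in unique}))
    mirna_ids = tuple(mirna_ids) if mirna_ids is not None else tuple(sorted({m for _, m in unique}))
    sm_pos = {s: k for k, s in enumerate(sm_ids)}
    mi_pos = {m: k for k, m in enumerate(mirna_ids)}
    values = np.zeros((len(sm_ids), len(mirna_ids)), dtype=np.int8)
    for s, m in unique:
        if s not in sm_pos:
            raise ValidationError(f"{path}: small molecule {s!r} not in id universe")
        if m not in mi_pos:
            raise ValidationError(f"{path}: miRNA {m!r} not in id universe")
        values[sm_pos[s], mi_pos[m]] = 1
    return AssociationMatrix(sm_ids, mirna_ids, values)


def write_associations(associations: AssociationMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("sm_id\tmirna_id\n")
        for s, m in associations.known_pairs():
            handle.write(f"{s}\t{m}\n")


def write_ranked_predictions(
    scores: ScoreMatrix, associations: AssociationMatrix, path
) -> None:
    """Ranked-prediction table: sm_id, mirna_id, score, rank, is_known,
    sorted by descending score with lexicographic tie-break."""
    rows = rank_predictions(scores, associations)
    df = pd.DataFrame(rows, columns=["sm_id", "mirna_id", "score", "rank", "is_known"])
    df.to_csv(path, sep="\t", index=False)


def write_catalog(path, catalog: IsomerCatalog | None = None) -> None:
    """Human-readable audit table of the isomer catalog."""
    catalog = catalog or enumerate_isomers()
    rows = [
        {
            "label": t.label,
            "n_nodes": t.n_nodes,
            "present_edges": ";".join("-".join(e) for e in sorted(t.present_edges)),
        }
        for t in catalog
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
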