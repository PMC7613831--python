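"""Readers and writers for the plain-text interchange formats of the pipeline.

Counts, metadata, atlas, target networks, peak tables and correlation
networks travel as TSV; spectra and intensity matrices as CSV (first column
ppm for spectra); planted truth and nested summaries as JSON.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .de import CountMatrix, DEGSet
from .deconv import AtlasMatrix, CELL_TYPES, DrugTargetNetwork
from .nmr import Spectrum


# --- counts ---------------------------------------------------------------


def write_counts(cm: CountMatrix, counts_path, metadata_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.metadata.to_csv(metadata_path, sep="\t")


def read_counts(counts_path, metadata_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return CountMatrix(counts, meta)


# --- atlas ----------------------------------------------------------------


def write_atlas(atlas: AtlasMatrix, path) -> None:
    atlas.abundance.to_csv(path, sep="\t")


def read_atlas(path) -> AtlasMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AtlasMatrix(df[list(CELL_TYPES)])


# --- drug/regulator networks ---------------------------------------------


def write_network(network: DrugTargetNetwork, path) -> None:
    rows = []
    for entity, targets in network.targets.items():
        for t in sorted(targets):
            sign = network.signs[entity][t] if network.signs else 0
            rows.append((entity, t, sign))
    pd.DataFrame(rows, columns=["source", "target", "expected_sign"]).to_csv(
        path, sep="\t", index=False
    )


def read_network(path) -> DrugTargetNetwork:
    df = pd.read_csv(path, sep="\t")
    targets: dict[str, set[str]] = {}
    signs: dict[str, dict[str, int]] = {}
    for source, sub in df.groupby("source"):
        targets[str(source)] = set(sub["target"].astype(str))
        signs[str(source)] = dict(zip(sub["target"].astype(str), sub["expected_sign"].astype(int)))
    return DrugTargetNetwork(targets=targets, signs=signs)


# --- spectra --------------------------------------------------------------


def write_spectra(spectra: list[Spectrum], spectra_path, metadata_path) -> None:
    wide = pd.DataFrame({"ppm": spectra[0].ppm})
    for s in spectra:
        if not np.array_equal(s.ppm, spectra[0].ppm):
            raise ValueError("all spectra must share one ppm axis for the wide CSV")
        wide[s.sample_id] = s.intensity
    wide.to_csv(spectra_path, index=False)
    pd.DataFrame(
        {"sample_id": [s.sample_id for s in spectra], "group": [s.group for s in spectra]}
    ).to_csv(metadata_path, sep="\t", index=False)


def read_spectra(spectra_path, metadata_path) -> list[Spectrum]:
    wide = pd.read_csv(spectra_path)
    meta = pd.read_csv(metadata_path, sep="\t").set_index("sample_id")
    ppm = wide["ppm"].to_numpy()
    return [
        Spectrum(ppm.copy(), wide[sid].to_numpy(), sid, str(meta.loc[sid, "group"]))
        for sid in wide.columns[1:]
    ]


# --- DEG sets and JSON blobs ----------------------------------------------


def write_degset(degs: DEGSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"contrast": degs.contrast, "fc": degs.fc, "alpha": degs.alpha,
             "directions": degs.directions},
            fh, indent=1,
        )


def read_degset(path) -> DEGSet:
    with open(path) as fh:
        d = json.load(fh)
    return DEGSet(contrast=d["contrast"], directions=d["directions"],
                  fc=d["fc"], alpha=d["alpha"])


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
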