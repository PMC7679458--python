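"""Channel metadata, edge annotation and network-pair summaries.

Channel anatomy is consumed as a user-supplied table — one row per channel
with MNI coordinates, an AAL-style anatomical label and an affiliation to
one of the seven canonical cortical networks (default-mode DMN,
frontoparietal FPN, dorsal-attention DAN, salience SN, ventral-attention
VAN, somatomotor SMN, limbic LN). Probe registration and atlas lookup are
out of scope; the shipped default table is a synthetic, illustrative layout
for a 46-channel frontal + bilateral temporo-parietal montage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError

NETWORKS = ("DMN", "FPN", "DAN", "SN", "VAN", "SMN", "LN")

# (channel 1-based, mni_x, mni_y, mni_z, AAL-style region, network)
# Synthetic/illustrative montage: channels 1-22 frontal, 23-34 right
# temporo-parietal, 35-46 left temporo-parietal. Coordinates are plausible
# but invented, not digitizer measurements.
_DEFAULT_CHANNELS = [
    (1, 38, 42, 28, "MFG.R", "DMN"),
    (2, 22, 54, 24, "SFG.R", "DMN"),
    (3, 18, 58, -12, "ORBsup.R", "LN"),
    (4, 48, 32, 6, "IFGtriang.R", "VAN"),
    (5, 34, 46, 18, "MFG.R", "SN"),
    (6, 20, 48, 38, "SFG.R", "FPN"),
    (7, -8, 54, 30, "SFGmed.L", "DMN"),
    (8, -36, 44, 26, "MFG.L", "DMN"),
    (9, -40, 36, 30, "MFG.L", "FPN"),
    (10, 8, 56, 26, "SFGmed.R", "DMN"),
    (11, -6, 56, -10, "ORBsupmed.L", "LN"),
    (12, -46, 34, 8, "IFGtriang.L", "VAN"),
    (13, -32, 40, 34, "MFG.L", "FPN"),
    (14, 42, 38, 32, "MFG.R", "FPN"),
    (15, 44, 6, 44, "PreCG.R", "SMN"),
    (16, -18, 52, 34, "SFG.L", "DMN"),
    (17, -20, 56, 22, "SFG.L", "DMN"),
    (18, -50, 14, 10, "IFGoperc.L", "VAN"),
    (19, 40, 50, -8, "ORBmid.R", "FPN"),
    (20, -42, 4, 46, "PreCG.L", "SMN"),
    (21, -40, 34, -12, "ORBinf.L", "LN"),
    (22, -22, 46, 40, "SFG.L", "FPN"),
    (23, 58, -14, 2, "STG.R", "VAN"),
    (24, 48, -26, 50, "PoCG.R", "SMN"),
    (25, 58, -36, 40, "SMG.R", "DAN"),
    (26, 48, -62, 34, "ANG.R", "DMN"),
    (27, 54, -54, 12, "MTG.R", "DMN"),
    (28, 62, -24, 10, "STG.R", "SMN"),
    (29, 50, -48, 46, "IPL.R", "FPN"),
    (30, 60, -30, 32, "SMG.R", "SN"),
    (31, 52, -8, 14, "ROL.R", "SMN"),
    (32, 60, -44, 4, "MTG.R", "DAN"),
    (33, 54, -38, -16, "ITG.R", "LN"),
    (34, 56, -50, 0, "MTG.R", "FPN"),
    (35, -58, -16, 4, "STG.L", "VAN"),
    (36, -46, -28, 50, "PoCG.L", "SMN"),
    (37, -48, -44, 48, "IPL.L", "DAN"),
    (38, -44, -52, 44, "IPL.L", "DMN"),
    (39, -46, -64, 32, "ANG.L", "DMN"),
    (40, -52, -46, 42, "IPL.L", "FPN"),
    (41, -62, -26, 12, "STG.L", "SMN"),
    (42, -58, -32, 34, "SMG.L", "SN"),
    (43, -54, -40, -14, "ITG.L", "LN"),
    (44, -58, -48, 2, "MTG.L", "DAN"),
    (45, -56, -54, 8, "MTG.L", "DMN"),
    (46, -44, -66, 36, "ANG.L", "DMN"),
]


def default_channel_table() -> pd.DataFrame:
    """Illustrative 46-channel metadata table (synthetic layout, see module doc)."""
    return pd.DataFrame(
        _DEFAULT_CHANNELS,
        columns=["channel", "mni_x", "mni_y", "mni_z", "region", "network"],
    )


def validate_channel_table(meta: pd.DataFrame) -> pd.DataFrame:
    required = {"channel", "region", "network"}
    if not required.issubset(meta.columns):
        raise InputError(f"channel table must have columns {sorted(required)}")
    if meta["channel"].duplicated().any():
        raise InputError("duplicate channel ids in channel table")
    bad = set(meta["network"]) - set(NETWORKS)
    if bad:
        raise InputError(f"unknown network labels {sorted(bad)}; allowed: {NETWORKS}")
    return meta


def load_channel_table(path) -> pd.DataFrame:
    return validate_channel_table(pd.read_csv(path, sep="\t"))


def write_channel_table(meta: pd.DataFrame, path) -> None:
    validate_channel_table(meta).to_csv(path, sep="\t", index=False)


def network_assignment(meta: pd.DataFrame) -> np.ndarray:
    """Channel -> network index (order of NETWORKS), sorted by channel id."""
    validate_channel_table(meta)
    nets = meta.sort_values("channel")["network"].map(NETWORKS.index)
    return nets.to_numpy()


def annotate_edges(edge_df: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Attach (region, network) of both endpoints to an edge table.

    ``edge_df`` needs 1-based ``chan_i``/``chan_j`` columns (as produced by
    the bootstrap edge table); unknown channel ids are an error.
    """
    validate_channel_table(meta)
    lookup = meta.set_index("channel")
    for col in ("chan_i", "chan_j"):
        unknown = set(edge_df[col]) - set(lookup.index)
        if unknown:
            raise InputError(f"channel id(s) {sorted(unknown)} missing from metadata")
    out = edge_df.copy()
    for side, col in (("seed", "chan_i"), ("target", "chan_j")):
        out[f"{side}_region"] = lookup.loc[out[col], "region"].to_numpy()
        out[f"{side}_network"] = lookup.loc[out[col], "network"].to_numpy()
    pair = [
        "-".join(sorted((a, b), key=NETWORKS.index))
        for a, b in zip(out["seed_network"], out["target_network"])
    ]
    out["network_pair"] = pair
    return out


def network_pair_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Counts of significant edges per unordered network pair, split by sign."""
    if "significant" in annotated.columns:
        annotated = annotated[annotated["significant"]]
    if len(annotated) == 0:
        return pd.DataFrame(columns=["network_pair", "sign", "n_edges"])
    return (
        annotated.groupby(["network_pair", "sign"], as_index=False)
        .size()
        .rename(columns={"size": "n_edges"})
        .sort_values(["network_pair", "sign"], ignore_index=True)
    )


def run_pipeline(config, outdir):
    """End-to-end orchestration; see :func:`nirscpm.pipeline.run_pipeline`."""
    from . import pipeline

    return pipeline.run_pipeline(config, outdir)
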