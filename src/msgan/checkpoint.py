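"""Self-describing checkpoint archives: weights + config + init seed in one npz."""

from __future__ import annotations

import json

import numpy as np


def save_checkpoint(module, config_dict: dict, seed: int, path) -> None:
    meta = json.dumps({"config": config_dict, "seed": int(seed)})
    arrays = {f"param/{k}": v for k, v in module.state_dict().items()}
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_checkpoint(path):
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k[len("param/"):]: archive[k] for k in archive.files if k.startswith("param/")}
    return state, meta["config"], meta["seed"]
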