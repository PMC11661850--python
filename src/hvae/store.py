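"""HDF5 stores for batches of steerable tensors.

Layout: one dataset ``flat`` holding the flat-vector export (ascending
degree, then channel, then m), the signature as a JSON attribute, optional
integer class labels, and free-form JSON metadata.  Synthetic and real
encoded data share this layout.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .tensors import SteerableTensor, TensorSignature

__all__ = ["load_tensor_store", "save_tensor_store"]


def save_tensor_store(path, tensor: SteerableTensor, labels=None, metadata: dict | None = None) -> None:
    flat = tensor.flatten()
    if flat.ndim == 1:
        flat = flat[None]
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("flat", data=flat)
        ds.attrs["signature"] = json.dumps([list(e) for e in tensor.signature.entries])
        if labels is not None:
            fh.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))
        if metadata:
            fh.attrs["metadata"] = json.dumps(metadata)


def load_tensor_store(path):
    """Returns (tensor, labels, metadata); labels/metadata may be None."""
    with h5py.File(path, "r") as fh:
        flat = fh["flat"][...]
        sig = TensorSignature(tuple(tuple(e) for e in json.loads(fh["flat"].attrs["signature"])))
        labels = fh["labels"][...] if "labels" in fh else None
        metadata = json.loads(fh.attrs["metadata"]) if "metadata" in fh.attrs else None
    return SteerableTensor.from_flat(flat, sig), labels, metadata
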