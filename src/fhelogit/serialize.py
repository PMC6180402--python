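"""Versioned JSON-with-base64 containers for key material and ciphertexts.

Each container carries a magic string, the parameter hash it was created
under, and coefficient blobs: fixed-width signed little-endian integers,
base64-encoded.  Toy-scale only; secret keys are stored alongside public
material (this artifact is a correctness testbed, not a deployment)."""

from __future__ import annotations

import base64
import json

from .fv import Ciphertext, KeySet
from .params import EncryptionParams, ParameterError
from .ring import RingElement

MAGIC_KEYS = "fhelogit/keys/v1"
MAGIC_CT = "fhelogit/ciphertext/v1"


def _blob(elem: RingElement) -> dict:
    width = (elem.modulus.bit_length() + 8) // 8 + 1
    raw = b"".join(
        int(c).to_bytes(width, "little", signed=True) for c in elem.coeffs
    )
    return {
        "n": elem.n,
        "modulus": str(elem.modulus),
        "width": width,
        "data": base64.b64encode(raw).decode(),
    }


def _unblob(d: dict) -> RingElement:
    raw = base64.b64decode(d["data"])
    width = d["width"]
    coeffs = tuple(
        int.from_bytes(raw[i * width:(i + 1) * width], "little", signed=True)
        for i in range(d["n"])
    )
    return RingElement(coeffs, int(d["modulus"]))


def _params_dict(p: EncryptionParams) -> dict:
    return {
        "n": p.n, "q": str(p.q), "p": p.p, "r": p.r,
        "sigma_err": p.sigma_err, "ternary_bound": p.ternary_bound,
        "relin_base": str(p.relin_base), "boot_e": p.boot_e,
        "fp_l": p.fp_l, "fp_f": p.fp_f,
    }


def _params_from(d: dict) -> EncryptionParams:
    return EncryptionParams(
        n=d["n"], q=int(d["q"]), p=d["p"], r=d["r"],
        sigma_err=d["sigma_err"], ternary_bound=d["ternary_bound"],
        relin_base=int(d["relin_base"]), boot_e=d["boot_e"],
        fp_l=d["fp_l"], fp_f=d["fp_f"],
    )


def ciphertext_to_json(ct: Ciphertext, params: EncryptionParams) -> str:
    return json.dumps({
        "magic": MAGIC_CT,
        "params_hash": params.key_hash,
        "size": ct.size,
        "q": str(ct.q),
        "t": str(ct.t),
        "parts": [_blob(p) for p in ct.parts],
    })


def ciphertext_from_json(blob: str, params: EncryptionParams) -> Ciphertext:
    d = json.loads(blob)
    if d.get("magic") != MAGIC_CT:
        raise ParameterError("not a ciphertext container")
    if d.get("params_hash") != params.key_hash:
        raise ParameterError("ciphertext was made under different parameters")
    return Ciphertext([_unblob(b) for b in d["parts"]], int(d["q"]), int(d["t"]))


def keyset_to_json(ks: KeySet) -> str:
    d = {
        "magic": MAGIC_KEYS,
        "params": _params_dict(ks.params),
        "params_hash": ks.params.key_hash,
        "sk": _blob(ks.sk),
        "pk": [_blob(ks.pk[0]), _blob(ks.pk[1])],
        "relin": [[_blob(a), _blob(b)] for a, b in ks.relin_keys],
        "galois": {str(e): [[_blob(a), _blob(b)] for a, b in keys]
                   for e, keys in ks.galois_keys.items()},
    }
    if ks.boot_key is not None:
        d["boot_key"] = {
            "e": ks.params.boot_e,
            "ct": json.loads(ciphertext_to_json(ks.boot_key, ks.params)),
        }
    return json.dumps(d)


def keyset_from_json(blob: str) -> KeySet:
    d = json.loads(blob)
    if d.get("magic") != MAGIC_KEYS:
        raise ParameterError("not a key container")
    params = _params_from(d["params"])
    ks = KeySet(
        params=params,
        sk=_unblob(d["sk"]),
        pk=(_unblob(d["pk"][0]), _unblob(d["pk"][1])),
        relin_keys=[(_unblob(a), _unblob(b)) for a, b in d["relin"]],
        galois_keys={int(e): [(_unblob(a), _unblob(b)) for a, b in keys]
                     for e, keys in d["galois"].items()},
    )
    if "boot_key" in d:
        ks.boot_key = ciphertext_from_json(json.dumps(d["boot_key"]["ct"]), params)
    return ks
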