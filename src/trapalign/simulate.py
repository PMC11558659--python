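"""Seeded synthetic sequence generation.

Emulates long-read-style query/reference pairs: a random reference and
mutated copies with independent per-position substitutions and
geometric-length insertions/deletions.  Everything is reproducible from
(parameters, seed); there is no hidden global randomness.

The divergence presets are named, not hard-coded: ``low``/``high`` bracket
the default ``long-read`` preset (5% substitutions, 2.5% insertion and
deletion events with mean length 1/0.7), which is the error scale of modern
long-read simulators.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InputError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MutationModel:
    """Per-position mutation rates and the indel length distribution.

    ``sub``/``ins``/``dele`` are event probabilities per original position;
    indel lengths are geometric with success parameter ``geom_p`` (mean
    1/geom_p).  ``seed`` makes the model fully reproducible.
    """

    sub: float = 0.05
    ins: float = 0.025
    dele: float = 0.025
    geom_p: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name, r in (("sub", self.sub), ("ins", self.ins), ("dele", self.dele)):
            if not 0.0 <= r < 1.0:
                raise InputError(f"rate {name}={r} outside [0, 1)")
        if self.sub + self.ins + self.dele >= 1.0:
            raise InputError("mutation rates must sum to less than 1")
        if not 0.0 < self.geom_p <= 1.0:
            raise InputError(f"geom_p={self.geom_p} outside (0, 1]")


#: named divergence presets
PRESETS: dict[str, MutationModel] = {
    "none": MutationModel(0.0, 0.0, 0.0),
    "low": MutationModel(0.02, 0.01, 0.01),
    "long-read": MutationModel(0.05, 0.025, 0.025),
    "high": MutationModel(0.15, 0.05, 0.05),
}


def preset(name: str, seed: int = 0) -> MutationModel:
    """Look up a divergence preset by name with a specific seed."""
    if name not in PRESETS:
        raise InputError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed)


def random_sequence(length: int, seed: int | np.random.Generator = 0) -> str:
    """Uniform i.i.d. sequence over {A, C, G, T}; deterministic per seed."""
    if length < 0:
        raise InputError(f"length must be >= 0, got {length}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate(seq: str, model: MutationModel) -> str:
    """Apply the mutation model left-to-right on the original coordinates.

    At each original position, independently: delete a geometric-length run
    with probability ``dele``, insert a geometric-length run of i.i.d. bases
    with probability ``ins``, and substitute the base (to a uniformly chosen
    *different* base) with probability ``sub``.
    """
    rng = np.random.default_rng(model.seed)
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        u = rng.random()
        if u < model.dele:
            i += int(rng.geometric(model.geom_p))
            continue
        if u < model.dele + model.ins:
            k = int(rng.geometric(model.geom_p))
            out.append(_BASES[rng.integers(0, 4, size=k)].tobytes().decode("ascii"))
        if rng.random() < model.sub:
            orig = seq[i].upper()
            choices = [b for b in "ACGT" if b != orig] or list("ACGT")
            out.append(choices[int(rng.integers(0, len(choices)))])
        else:
            out.append(seq[i])
        i += 1
    return "".join(out)


def dataset(n_sequences: int, length: int, model: MutationModel) -> list[str]:
    """One random seed sequence plus n-1 independently mutated copies."""
    if n_sequences < 1:
        raise InputError("need at least one sequence")
    root = np.random.SeedSequence(model.seed)
    children = root.spawn(n_sequences)
    base = random_sequence(length, np.random.default_rng(children[0]))
    out = [base]
    for k in range(1, n_sequences):
        child_seed = int(children[k].generate_state(1)[0] % (2**31))
        out.append(mutate(base, replace(model, seed=child_seed)))
    return out


def mutated_pair(
    length: int, preset_name: str, seed: int
) -> tuple[str, str]:
    """Convenience: a reference and one mutated (or independent) query.

    With preset ``"none"`` the query is an *independent* random sequence of
    the same length, modelling unrelated inputs.
    """
    model = preset(preset_name, seed)
    ref = random_sequence(length, np.random.default_rng(np.random.SeedSequence(seed)))
    if preset_name == "none":
        qry = random_sequence(length, np.random.default_rng(np.random.SeedSequence((seed, 1))))
    else:
        qry = mutate(ref, replace(model, seed=seed + 1))
    return ref, qry
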