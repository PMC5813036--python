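"""Named, reproducible child random streams derived from one master seed.

Every stochastic stage of the pipeline (genotype sampling, factor sampling,
status assignment, chip masking, conditional score simulation) pulls from its
own named stream so that a stage can be re-run in isolation and still produce
the same draws as inside the full pipeline.
"""
from __future__ import annotations

import numpy as np

#: canonical stream order — do not reorder, it defines reproducibility
STREAMS = (
    "genotypes",
    "latent_genotypes",
    "factors",
    "status",
    "masking",
    "grs24_sim",
    "grs68_sim",
)


def child_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Return one independent :class:`numpy.random.Generator` per named stage."""
    children = np.random.SeedSequence(seed).spawn(len(STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(STREAMS, children)}
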