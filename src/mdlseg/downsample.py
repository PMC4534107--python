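"""Read-count thinning: emulate shallower sequencing of the same library.

Retaining each read independently with probability f is equivalent, at the
count level, to drawing the new total coverage of a site as
Binomial(total, f) and the new methylated count as a hypergeometric draw
of that many reads from the site's methylated/unmethylated pool — no raw
reads are needed. Thinning is unbiased for the methylation level and
reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .io_methylome import ChromSites, MethylomeTrack


def thin_counts(track: MethylomeTrack, fraction: float, seed: int) -> MethylomeTrack:
    """Thin every site's reads to an expected ``fraction`` of the original.

    Sites whose thinned coverage reaches zero are dropped, mirroring how
    uncovered sites are absent from real call files.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    chroms: dict[str, ChromSites] = {}
    for chrom in track.chrom_names():
        c = track.chroms[chrom]
        if fraction == 1.0:
            chroms[chrom] = ChromSites(c.pos.copy(), c.meth.copy(), c.total.copy())
            continue
        new_total = rng.binomial(c.total, fraction)
        new_meth = rng.hypergeometric(
            np.maximum(c.meth, 0), c.total - c.meth, np.maximum(new_total, 1)
        )
        new_meth = np.where(new_total > 0, new_meth, 0)
        keep = new_total > 0
        if keep.any():
            chroms[chrom] = ChromSites(c.pos[keep], new_meth[keep], new_total[keep])
    return MethylomeTrack(chroms=chroms, sample=track.sample, min_depth=None)
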