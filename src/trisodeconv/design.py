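"""Experiment design: lines, batches, pools and the organoid roster.

The study design this package emulates compares three disomic and three
trisomic isogenic iPSC subclone lines. In each of four independent
differentiation batches, four pools of 12 organoids are generated per line;
two of the four pools per line per batch are bulk RNA-sequenced and the rest
are reserved for other assays. With the defaults this yields 48 sequenced
samples (6 lines x 4 batches x 2 pools) and 576 organoids per trisomy state
(3 lines x 12 organoids x 4 pools x 4 batches).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the pooled-organoid experiment design."""

    n_disomic_lines: int = 3
    n_trisomic_lines: int = 3
    n_batches: int = 4
    pools_per_line_per_batch_sequenced: int = 2
    pools_per_line_per_batch_total: int = 4
    organoids_per_pool: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_disomic_lines",
            "n_trisomic_lines",
            "n_batches",
            "pools_per_line_per_batch_sequenced",
            "pools_per_line_per_batch_total",
            "organoids_per_pool",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.pools_per_line_per_batch_sequenced > self.pools_per_line_per_batch_total:
            raise ValueError("sequenced pools per line/batch cannot exceed total pools")

    @property
    def n_lines(self) -> int:
        return self.n_disomic_lines + self.n_trisomic_lines

    @property
    def n_sequenced_samples(self) -> int:
        return self.n_lines * self.n_batches * self.pools_per_line_per_batch_sequenced

    def n_organoids(self, trisomic: bool) -> int:
        n_lines = self.n_trisomic_lines if trisomic else self.n_disomic_lines
        return (
            n_lines
            * self.organoids_per_pool
            * self.pools_per_line_per_batch_total
            * self.n_batches
        )


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced bulk RNA-seq sample: a pool of organoids from one line."""

    sample_id: str
    line_id: str
    trisomic: bool
    batch: str
    pool: str
    n_organoids: int


@dataclass(frozen=True)
class OrganoidRecord:
    """One organoid in the full roster (sequenced or reserved pool)."""

    organoid_id: str
    line_id: str
    trisomic: bool
    batch: str
    pool: str
    sequenced: bool


@dataclass
class Design:
    """Sequenced-sample list plus the full organoid roster."""

    config: DesignConfig
    samples: list[SampleMeta] = field(default_factory=list)
    roster: list[OrganoidRecord] = field(default_factory=list)

    @property
    def line_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.line_id not in seen:
                seen.append(s.line_id)
        return seen

    def trisomic_lines(self) -> list[str]:
        return [l for l in self.line_ids if self.line_trisomic(l)]

    def disomic_lines(self) -> list[str]:
        return [l for l in self.line_ids if not self.line_trisomic(l)]

    def line_trisomic(self, line_id: str) -> bool:
        for s in self.samples:
            if s.line_id == line_id:
                return s.trisomic
        raise KeyError(f"unknown line {line_id!r}")


def make_design(config: DesignConfig | None = None) -> Design:
    """Enumerate sequenced samples and the full organoid roster.

    Deterministic given ``config``: line, batch and pool labels are assigned
    in a fixed order (disomic lines first). The first
    ``pools_per_line_per_batch_sequenced`` pools of each line x batch are the
    sequenced ones; the remaining pools are reserved.
    """
    config = config or DesignConfig()
    lines = [(f"dis{i + 1}", False) for i in range(config.n_disomic_lines)] + [
        (f"tri{i + 1}", True) for i in range(config.n_trisomic_lines)
    ]
    samples: list[SampleMeta] = []
    roster: list[OrganoidRecord] = []
    for b in range(1, config.n_batches + 1):
        batch = f"org{b}"
        for line_id, trisomic in lines:
            for p in range(1, config.pools_per_line_per_batch_total + 1):
                pool = f"p{p}"
                sequenced = p <= config.pools_per_line_per_batch_sequenced
                if sequenced:
                    samples.append(
                        SampleMeta(
                            sample_id=f"{line_id}_{batch}_{pool}",
                            line_id=line_id,
                            trisomic=trisomic,
                            batch=batch,
                            pool=pool,
                            n_organoids=config.organoids_per_pool,
                        )
                    )
                for o in range(1, config.organoids_per_pool + 1):
                    roster.append(
                        OrganoidRecord(
                            organoid_id=f"{line_id}_{batch}_{pool}_o{o}",
                            line_id=line_id,
                            trisomic=trisomic,
                            batch=batch,
                            pool=pool,
                            sequenced=sequenced,
                        )
                    )
    return Design(config=config, samples=samples, roster=roster)
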