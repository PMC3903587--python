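"""Synthetic data: coupled oscillators and outcome-level trial generation.

Two tiers:

* Signal level -- :func:`simulate_coupled_signals` produces multichannel
  narrowband oscillations whose pairwise phase coupling follows a
  prescribed :class:`CouplingTopology`. Coupled channels receive a
  quarter-cycle-delayed admixture of their neighbor's oscillation, so that
  genuine interactions carry a nonzero phase lag and are visible to the
  PLI, while an instantaneous (zero-lag) copy is not. Topologies come from
  a weighted Watts-Strogatz construction whose rewiring probability moves
  the network from ordered (high clustering, long paths) through
  small-world to random.

* Outcome level -- :func:`simulate_trial_outcomes` generates a tidy
  2-arm, 3-visit, multi-site longitudinal dataset of network outcomes
  (arm-by-visit means plus site, subject and residual Gaussian effects,
  with missing baselines and monotone dropout), for fast, exactly
  controlled testing of the trial statistics.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    COMMON_SAMPLE_RATES,
    MONTAGE_1020,
    VISITS,
    CouplingTopology,
    EEGRecording,
    TrialSimConfig,
)


def watts_strogatz_topology(n: int, k: int, p: float,
                            w_strong: float = 0.4, w_weak: float = 0.0,
                            rng: np.random.Generator | None = None) -> CouplingTopology:
    """Weighted Watts-Strogatz coupling matrix.

    A ring lattice of ``n`` nodes, each coupled at strength ``w_strong``
    to its ``k`` nearest neighbors on a background of ``w_weak``; every
    lattice edge is then, with probability ``p``, removed and re-placed
    on a uniformly random vacant node pair (non-self, non-duplicate), so
    that at p=1 the strong-edge placement is uniform and coincides in
    distribution with the weight-shuffle surrogate null. p=0 gives the
    ordered regime, p=1 the random regime, small p the small-world
    regime. The strong-edge count is conserved for every p.
    """
    if rng is None:
        rng = np.random.default_rng()
    if k % 2 != 0 or not 0 < k < n:
        raise ValueError(f"k must be even and 0 < k < n (got k={k}, n={n})")
    if not 0 <= p <= 1:
        raise ValueError("rewiring probability must lie in [0, 1]")
    if not w_strong > w_weak >= 0:
        raise ValueError("need w_strong > w_weak >= 0")
    edges = set()
    for i in range(n):
        for d in range(1, k // 2 + 1):
            edges.add(frozenset((i, (i + d) % n)))
    edges = sorted(tuple(sorted(e)) for e in edges)
    edge_set = set(edges)
    all_pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    # Two phases (remove all rewired edges, then re-place) so that at p=1
    # the strong edges form a uniformly random subset of the node pairs.
    marked = [e for e in edges if rng.random() < p]
    for e in marked:
        edge_set.discard(e)
    for _ in marked:
        vacant = [pr for pr in all_pairs if pr not in edge_set]
        if vacant:
            edge_set.add(vacant[rng.integers(len(vacant))])
    kappa = np.full((n, n), w_weak, dtype=float)
    np.fill_diagonal(kappa, 0.0)
    for (i, j) in edge_set:
        kappa[i, j] = kappa[j, i] = w_strong
    return CouplingTopology(kappa=kappa, rewiring_p=p, base_k=k)


def simulate_coupled_signals(
    topology: CouplingTopology,
    duration_s: float,
    rate: float = 200.0,
    band_center_hz: float = 19.0,
    noise_sd: float = 0.3,
    rng: np.random.Generator | None = None,
    freq_spread_hz: float = 4.0,
    phase_jitter: float = 0.2,
    amplitude_uv: float = 30.0,
    labels: list[str] | None = None,
    subject_id: str | None = None,
    visit: str | None = None,
) -> EEGRecording:
    """Multichannel narrowband signals with prescribed phase coupling.

    Each channel carries an oscillator near ``band_center_hz``. Channel
    frequencies are spread evenly across ``band_center_hz +/-
    freq_spread_hz`` (randomly assigned to channels) and each phase
    performs a slow Brownian jitter, so that uncoupled channel pairs have
    a drifting phase difference and expected PLI near zero. For a coupled
    pair (i, j) with strength kappa_ij, the higher-indexed channel mixes
    in the lower-indexed channel's oscillation delayed by roughly a
    quarter cycle (a directed driver convention: a symmetric exchange
    would swap the two sources and produce no phase-locking), making the
    pair's expected PLI monotone increasing in kappa_ij. The per-edge
    delay is drawn uniformly from one eighth to three eighths of a cycle:
    were every edge delayed identically, two channels driven by a common
    neighbor would receive the same delayed source at zero relative lag
    and their PLI would be suppressed, inverting the clustering of the
    induced network relative to its coupling topology.

    ``noise_sd`` is the white measurement-noise standard deviation
    relative to the oscillation amplitude (``amplitude_uv`` microvolts).
    """
    if rng is None:
        rng = np.random.default_rng()
    if rate <= 2 * band_center_hz:
        raise ValueError(
            f"rate {rate} Hz must exceed twice the band center "
            f"{band_center_hz} Hz (aliasing)"
        )
    n = topology.n_nodes
    cycle = rate / band_center_hz  # samples per cycle at the band center
    max_delay = int(np.ceil(cycle * 3.0 / 8.0))
    n_samples = int(round(duration_s * rate))
    n_total = n_samples + max_delay
    t = np.arange(n_total) / rate
    # Distinct channel frequencies: even spacing, shuffled assignment.
    freqs = band_center_hz + np.linspace(-freq_spread_hz, freq_spread_hz, n)
    rng.shuffle(freqs)
    theta0 = rng.uniform(-np.pi, np.pi, size=n)
    jitter = np.cumsum(
        rng.normal(0.0, phase_jitter / np.sqrt(rate), size=(n, n_total)),
        axis=1,
    )
    phases = 2 * np.pi * freqs[:, None] * t[None, :] + theta0[:, None] + jitter
    sources = np.cos(phases)
    # Driver convention: the lower-indexed channel of a coupled pair
    # drives the higher-indexed one, delayed by 1/8 to 3/8 of a cycle.
    drive = np.tril(topology.kappa, k=-1)  # drive[j, i] = kappa_ij, i < j
    row_sum = drive.sum(axis=1)
    mix_total = np.minimum(row_sum, 0.95)
    scale = np.where(row_sum > 0, mix_total / np.maximum(row_sum, 1e-12), 0.0)
    delays = np.round(
        rng.uniform(cycle / 8.0, cycle * 3.0 / 8.0, size=(n, n))
    ).astype(int)
    X = np.empty((n, n_samples))
    for j in range(n):
        x = (1.0 - mix_total[j]) * sources[j, max_delay:max_delay + n_samples]
        for i in np.flatnonzero(drive[j]):
            d = delays[j, i]
            x = x + (scale[j] * drive[j, i]) * sources[
                i, max_delay - d:max_delay - d + n_samples]
        X[j] = x
    X = amplitude_uv * X + amplitude_uv * noise_sd * rng.normal(size=X.shape)
    if labels is None:
        labels = (MONTAGE_1020[:n] if n <= len(MONTAGE_1020)
                  else [f"ch{i}" for i in range(n)])
    return EEGRecording(data=X, rate=rate, labels=list(labels),
                        subject_id=subject_id, visit=visit)


def _assign_sites(n_subjects: int, n_sites: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Roughly balanced random site assignment."""
    base = np.repeat(np.arange(n_sites), int(np.ceil(n_subjects / n_sites)))
    rng.shuffle(base)
    return base[:n_subjects]


def simulate_trial_outcomes(cfg: TrialSimConfig) -> pd.DataFrame:
    """Tidy longitudinal dataset of simulated network outcomes.

    Columns: subject_id, site_id, group, visit, outcome, baseline_value,
    sample_rate_hz, memory_z. One row per subject x observed visit;
    missing baselines leave baseline rows out and set baseline_value to
    NaN on the post-baseline rows; dropout removes a subject's rows from
    the dropout visit onward.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = ["control"] * cfg.n_control + ["active"] * cfg.n_active
    n = len(groups)
    sites = _assign_sites(n, cfg.n_sites, rng)
    site_rate = rng.choice(COMMON_SAMPLE_RATES, size=cfg.n_sites)
    site_eff = rng.normal(0.0, cfg.sd_site, size=cfg.n_sites)
    subj_eff = rng.normal(0.0, cfg.sd_subject, size=n)
    means = {"control": cfg.mean_control, "active": cfg.mean_active}

    miss_base = rng.random(n) < cfg.missing_baseline_frac
    drops = rng.random(n) < cfg.dropout_frac
    # Monotone dropout: missing from a uniformly chosen post-baseline visit on.
    drop_from = np.where(drops, rng.integers(1, 3, size=n), 99)

    rows = []
    for s in range(n):
        g = groups[s]
        sid = f"S{s + 1:04d}"
        base_out = np.nan
        subject_rows = []
        for v, visit in enumerate(VISITS):
            out = (means[g][v] + site_eff[sites[s]] + subj_eff[s]
                   + rng.normal(0.0, cfg.sd_residual))
            if visit == "baseline":
                base_out = out
            observed = not (visit == "baseline" and miss_base[s]) \
                and v < drop_from[s]
            if observed:
                subject_rows.append({
                    "subject_id": sid,
                    "site_id": f"site{sites[s] + 1:02d}",
                    "group": g,
                    "visit": visit,
                    "outcome": out,
                })
        baseline_value = np.nan if miss_base[s] else base_out
        for row in subject_rows:
            row["baseline_value"] = baseline_value
            row["sample_rate_hz"] = float(site_rate[sites[s]])
        rows.extend(subject_rows)
    df = pd.DataFrame(rows)
    center = float(np.mean(cfg.mean_control + cfg.mean_active))
    if cfg.memory_link == "none":
        df["memory_z"] = rng.normal(0.0, 1.0, size=len(df))
    elif cfg.memory_link == "linear":
        df["memory_z"] = (10.0 * (df["outcome"] - center)
                          + rng.normal(0.0, cfg.memory_noise_sd, size=len(df)))
    else:  # quadratic
        df["memory_z"] = (-300.0 * (df["outcome"] - center) ** 2
                          + rng.normal(0.0, cfg.memory_noise_sd, size=len(df)))
    return df


def simulate_full_trial(
    cfg: TrialSimConfig,
    topology_schedule: dict[str, tuple[float, float, float]],
    out_dir: str | Path,
    n_channels: int = 19,
    lattice_k: int = 6,
    coupling_strong: float = 0.4,
    n_epochs: int = 4,
    epoch_len: int = 4096,
    rate: float = 200.0,
    band_center_hz: float = 19.0,
    noise_sd: float = 0.3,
) -> pd.DataFrame:
    """Write a directory of ASCII EEG recordings plus a manifest CSV.

    ``topology_schedule`` maps each arm to per-visit Watts-Strogatz
    rewiring probabilities, e.g. ``{"control": (0.1, 0.3, 0.6), "active":
    (0.1, 0.1, 0.1)}`` -- the control arm's coupling graph degrades from
    small-world toward random over the trial while the active arm's stays
    put. Each subject's visit topologies are drawn from a persistent
    subject-specific randomness stream, so a higher scheduled rewiring
    probability rewires a superset of the edges rewired at earlier
    visits: the subject's own network degrades progressively rather than
    being resampled from scratch, and a constant schedule keeps the
    subject's topology fixed across visits. Signal noise is independent
    per visit.

    Returns the manifest (also written as ``manifest.csv``): columns
    file, subject_id, site_id, group, visit, rate.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    groups = ["control"] * cfg.n_control + ["active"] * cfg.n_active
    n = len(groups)
    sites = _assign_sites(n, cfg.n_sites, rng)
    drops = rng.random(n) < cfg.dropout_frac
    drop_from = np.where(drops, rng.integers(1, 3, size=n), 99)
    duration_s = (n_epochs * epoch_len) / rate + 1.0
    labels = (MONTAGE_1020[:n_channels] if n_channels <= len(MONTAGE_1020)
              else [f"ch{i}" for i in range(n_channels)])
    topo_seeds = np.random.SeedSequence(cfg.seed).generate_state(n) % (2 ** 31)
    rows = []
    for s in range(n):
        g = groups[s]
        sid = f"S{s + 1:04d}"
        for v, visit in enumerate(VISITS):
            if v >= drop_from[s]:
                continue
            p = topology_schedule[g][v]
            # Fresh generator from the subject's seed at every visit:
            # identical rewiring uniforms make the rewired edge sets
            # nested in the scheduled probability.
            topo = watts_strogatz_topology(
                n_channels, lattice_k, p, w_strong=coupling_strong,
                w_weak=0.0, rng=np.random.default_rng(topo_seeds[s]),
            )
            rec = simulate_coupled_signals(
                topo, duration_s, rate=rate, band_center_hz=band_center_hz,
                noise_sd=noise_sd, rng=rng, labels=labels,
                subject_id=sid, visit=visit,
            )
            fname = f"{sid}_{visit}.txt"
            header = " ".join(labels)
            np.savetxt(out_dir / fname, rec.data.T, fmt="%.3f",
                       header=header, comments="")
            rows.append({
                "file": fname, "subject_id": sid,
                "site_id": f"site{sites[s] + 1:02d}", "group": g,
                "visit": visit, "rate": rate,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


#: Rewiring schedule used by the end-to-end fixture: the control arm's
#: coupling degrades toward random; the active arm stays small-world.
DEFAULT_SCHEDULE = {"control": (0.1, 0.3, 0.6), "active": (0.1, 0.1, 0.1)}
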