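"""Protocol orchestration: baselines, feedback blocks, sham replay, logs.

One training day is: a 1-min start baseline (display disabled; used to
calibrate ASR and to warm up the controller's dynamic range), six 5-min
feedback blocks separated by 2-3 min breaks, and a 1-min end baseline.
The dynamic range at the end of each block carries into the next; breaks
are clock gaps only. A full protocol is eight such days.

In sham mode the participant's own EEG is still acquired, cleaned and run
through the controller (so their p and hypothetical f are logged), but the
*displayed* values are replayed from a matched participant's log, which is
what drives the subject's feedback response.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from fmtheta._version import __version__ as _pkg_version
from fmtheta.asr import ASRParams, ASRProcessor, asr_calibrate
from fmtheta.controller import (
    ThetaPowerConfig,
    baseline_warmup,
    feedback_update,
)
from fmtheta.sim_subject import MONTAGE, SubjectModel, SubjectStream
from fmtheta.stream_chain import EEGChunk, StreamChain

_BAND_BINS = {"theta": (4, 7), "alpha": (8, 12), "beta": (12, 18)}


@dataclass(frozen=True)
class SessionPlan:
    """Timing and mode of one training day."""

    start_baseline: float = 60.0
    n_blocks: int = 6
    block_len: float = 300.0
    break_len: float = 150.0
    end_baseline: float = 60.0
    n_sessions: int = 8
    mode: str = "feedback"            # "feedback" | "sham"
    chunk_len: float = 0.25
    native_rate: float = 2048.0
    asr_cutoff: float = 5.0
    asr_min_baseline: float = 30.0
    warmup_half_range: float = 1.0

    def validate(self) -> None:
        if self.mode not in ("feedback", "sham"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("start_baseline", "block_len", "end_baseline",
                     "chunk_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def training_seconds(self) -> float:
        return self.n_blocks * self.block_len


@dataclass
class BlockLog:
    """Per-update arrays for one segment (baseline or feedback block)."""

    times: np.ndarray
    p: np.ndarray
    f_raw: np.ndarray
    f_capped: np.ndarray
    f_displayed: np.ndarray
    shown: np.ndarray          # what the subject actually saw (sham-aware)
    l: np.ndarray
    h: np.ndarray
    alpha_p: np.ndarray
    beta_p: np.ndarray

    def __len__(self) -> int:
        return len(self.p)

    @staticmethod
    def from_records(recs: list[dict]) -> "BlockLog":
        keys = ("times", "p", "f_raw", "f_capped", "f_displayed", "shown",
                "l", "h", "alpha_p", "beta_p")
        cols = {k: [] for k in keys}
        for r in recs:
            for k in keys:
                cols[k].append(r[k])
        return BlockLog(**{k: np.asarray(v) for k, v in cols.items()})

    def band_log_power(self, band: str) -> np.ndarray:
        if band == "theta":
            return self.p
        if band == "alpha":
            return self.alpha_p
        if band == "beta":
            return self.beta_p
        raise KeyError(f"unknown band {band!r}")


@dataclass
class SessionLog:
    """Everything recorded during one training day."""

    subject_id: str
    session_index: int
    mode: str
    plan: SessionPlan
    seed: int
    start_baseline: BlockLog
    blocks: list[BlockLog]
    end_baseline: BlockLog
    software_version: str = _pkg_version

    def all_block_band_power(self, band: str = "theta") -> np.ndarray:
        return np.concatenate([b.band_log_power(band) for b in self.blocks])


class _BandPowerBank:
    """Sliding 1 s ring buffer over Fz plus per-band log-power extraction
    from a single Hamming-tapered FFT."""

    def __init__(self, config: ThetaPowerConfig):
        from scipy import signal as sps

        self.config = config
        n = config.window_samples
        self._taper = sps.get_window("hamming", n, fftbins=True)
        self._buf = np.zeros(n)
        self._filled = 0

    def push(self, samples: np.ndarray) -> bool:
        k = len(samples)
        self._buf = np.roll(self._buf, -k)
        self._buf[-k:] = samples
        self._filled = min(self._filled + k, len(self._buf))
        return self._filled == len(self._buf)

    def powers(self) -> dict[str, float]:
        spec = np.fft.rfft(self._buf * self._taper)
        logp = 10.0 * np.log10(np.maximum(np.abs(spec) ** 2, 1e-300))
        out = {"theta": float(np.mean(logp[list(self.config.target_bins)]))}
        bin_hz = self.config.sample_rate / len(self._buf)
        for band, (lo, hi) in _BAND_BINS.items():
            if band == "theta":
                continue
            k0, k1 = int(round(lo / bin_hz)), int(round(hi / bin_hz))
            out[band] = float(np.mean(logp[k0:k1 + 1]))
        return out


def run_session(source, plan: SessionPlan, seed: int = 0,
                subject_id: str = "S01", session_index: int = 1,
                sham_source: SessionLog | None = None,
                theta_config: ThetaPowerConfig | None = None) -> SessionLog:
    """Run one full training day against a simulated subject.

    ``source`` is a :class:`SubjectModel` (a fresh stream is created) or a
    :class:`SubjectStream` (state carries across days, enabling per-session
    learning). Sham mode requires ``sham_source``, a complete log of
    identical plan shape whose displayed values are replayed.
    """
    plan.validate()
    if plan.mode == "sham":
        if sham_source is None:
            raise ValueError("sham mode requires a sham_source log")
        if (len(sham_source.blocks) != plan.n_blocks
                or any(len(b) != int(round(plan.block_len / plan.chunk_len))
                       for b in sham_source.blocks)):
            raise ValueError("sham_source shape does not match the plan")

    if isinstance(source, SubjectModel):
        stream = SubjectStream(source, seed=seed)
    elif isinstance(source, SubjectStream):
        stream = source
    else:
        raise TypeError("source must be a SubjectModel or SubjectStream")

    cfg = theta_config or ThetaPowerConfig()
    chain = StreamChain(native_rate=stream.subject.sample_rate,
                        target_rate=cfg.sample_rate)
    chain_state = chain.new_state()
    bank = _BandPowerBank(cfg)
    fz = MONTAGE.index("Fz")

    def acquire(duration: float, asr_proc, on_update) -> list[dict]:
        """Stream `duration` seconds through the chain; call on_update at
        each 4 Hz tick; return the per-update records."""
        recs: list[dict] = []
        n_chunks = int(round(duration / plan.chunk_len))
        for i in range(n_chunks):
            raw, _ = stream.next_chunk(plan.chunk_len)
            chunk = EEGChunk(raw, stream.subject.sample_rate, MONTAGE)
            out = chain.process_chunk(chunk, chain_state)
            if asr_proc is not None:
                out = asr_proc.process(out)
            if bank.push(out.data[fz]):
                rec = on_update(bank.powers(), len(recs))
                if rec is not None:
                    recs.append(rec)
        return recs

    # ---- start baseline: collect cleaned data for ASR calibration and
    # p values for the dynamic-range warm-up (display disabled) ----
    baseline_out: list[np.ndarray] = []
    baseline_ps: list[dict] = []

    def baseline_update(powers, i):
        baseline_ps.append(powers)
        return {"times": np.nan, "p": powers["theta"], "f_raw": np.nan,
                "f_capped": np.nan, "f_displayed": 0.0, "shown": 0.0,
                "l": np.nan, "h": np.nan, "alpha_p": powers["alpha"],
                "beta_p": powers["beta"]}

    n_chunks = int(round(plan.start_baseline / plan.chunk_len))
    start_recs: list[dict] = []
    for i in range(n_chunks):
        raw, _ = stream.next_chunk(plan.chunk_len)
        chunk = EEGChunk(raw, stream.subject.sample_rate, MONTAGE)
        out = chain.process_chunk(chunk, chain_state)
        baseline_out.append(out.data)
        if bank.push(out.data[fz]):
            start_recs.append(baseline_update(bank.powers(), i))

    baseline_data = np.concatenate(baseline_out, axis=1)
    model = asr_calibrate(
        EEGChunk(baseline_data, cfg.sample_rate, MONTAGE),
        ASRParams(cutoff=plan.asr_cutoff),
        min_duration=plan.asr_min_baseline)
    asr_proc = ASRProcessor(model)

    fb_state = baseline_warmup([r["p"] for r in start_recs],
                               half_range=plan.warmup_half_range)

    # ---- feedback blocks ----
    blocks: list[BlockLog] = []
    clock = plan.start_baseline
    for b in range(plan.n_blocks):
        fb_state = dataclasses.replace(fb_state, f_displayed_prev=0.0)
        sham_block = sham_source.blocks[b] if plan.mode == "sham" else None

        def block_update(powers, i, _sham=sham_block, _t0=clock):
            nonlocal fb_state
            sample, fb_state = feedback_update(powers["theta"], fb_state)
            shown = (float(_sham.f_displayed[i]) if _sham is not None
                     else sample.f_displayed)
            stream.apply_feedback(shown)
            return {"times": _t0 + (i + 1) * cfg.update_period,
                    "p": sample.p, "f_raw": sample.f_raw,
                    "f_capped": sample.f_capped,
                    "f_displayed": sample.f_displayed, "shown": shown,
                    "l": sample.l, "h": sample.h,
                    "alpha_p": powers["alpha"], "beta_p": powers["beta"]}

        recs = acquire(plan.block_len, asr_proc, block_update)
        blocks.append(BlockLog.from_records(recs))
        clock += plan.block_len + plan.break_len  # break: clock gap only

    # ---- end baseline: display disabled, range keeps updating ----
    def end_update(powers, i):
        nonlocal fb_state
        sample, fb_state = feedback_update(powers["theta"], fb_state)
        return {"times": np.nan, "p": sample.p, "f_raw": sample.f_raw,
                "f_capped": sample.f_capped, "f_displayed": 0.0,
                "shown": 0.0, "l": sample.l, "h": sample.h,
                "alpha_p": powers["alpha"], "beta_p": powers["beta"]}

    end_recs = acquire(plan.end_baseline, asr_proc, end_update)

    return SessionLog(
        subject_id=subject_id, session_index=session_index, mode=plan.mode,
        plan=plan, seed=seed,
        start_baseline=BlockLog.from_records(start_recs),
        blocks=blocks,
        end_baseline=BlockLog.from_records(end_recs))


def replay_sham(source_log: SessionLog, block_index: int) -> np.ndarray:
    """Displayed-value sequence of one block (0-based index), exactly as a
    yoked sham participant would see it."""
    if not 0 <= block_index < len(source_log.blocks):
        raise IndexError(
            f"block {block_index} not in log with "
            f"{len(source_log.blocks)} blocks")
    return source_log.blocks[block_index].f_displayed.copy()


def run_protocol(subject: SubjectModel, plan: SessionPlan, seed: int,
                 subject_id: str = "S01",
                 sham_logs: list[SessionLog] | None = None
                 ) -> list[SessionLog]:
    """Run all ``plan.n_sessions`` days for one subject, carrying the
    subject's learning state (attention set-point) across days."""
    stream = SubjectStream(subject, seed=seed)
    logs = []
    for s in range(1, plan.n_sessions + 1):
        log = run_session(
            stream, plan, seed=seed, subject_id=subject_id,
            session_index=s,
            sham_source=None if sham_logs is None else sham_logs[s - 1])
        logs.append(log)
        stream.advance_session()
    return logs


def run_matched_experiment(n_pairs: int, plan: SessionPlan, seed: int,
                           learner: SubjectModel | None = None,
                           sham_subject: SubjectModel | None = None,
                           subject_sd: float = 0.15,
                           ) -> tuple[dict[str, list[SessionLog]],
                                      dict[str, list[SessionLog]]]:
    """Simulate a full matched-pair cohort: ``n_pairs`` feedback subjects
    and their yoked sham partners.

    Each feedback subject runs the whole protocol first; the matched sham
    partner then replays those displayed values session by session. Between
    subjects, the initial attention set-point is jittered by ``subject_sd``
    (inter-individual variability). Sham partners share the feedback
    subjects' signal parameters but have a zero session learning rate.

    Returns ``(feedback_logs, sham_logs)`` keyed by subject id.
    """
    import dataclasses as _dc

    base = learner if learner is not None else SubjectModel(
        sample_rate=plan.native_rate)
    sham_base = sham_subject if sham_subject is not None else _dc.replace(
        base, session_learning_rate=0.0)
    rng = np.random.default_rng(seed)
    fb_logs: dict[str, list[SessionLog]] = {}
    sham_logs: dict[str, list[SessionLog]] = {}
    sham_plan = _dc.replace(plan, mode="sham")
    for pair in range(n_pairs):
        att = float(np.clip(base.attention_state
                            + subject_sd * rng.standard_normal(), 0.05, 0.9))
        s_fb = int(rng.integers(0, 2**31 - 1))
        s_sh = int(rng.integers(0, 2**31 - 1))
        fb_subj = _dc.replace(base, attention_state=att, rng_seed=s_fb)
        fid = f"NF{pair + 1:02d}"
        fb_logs[fid] = run_protocol(fb_subj, plan, seed=s_fb,
                                    subject_id=fid)
        att2 = float(np.clip(sham_base.attention_state
                             + subject_sd * rng.standard_normal(),
                             0.05, 0.9))
        sh_subj = _dc.replace(sham_base, attention_state=att2,
                              rng_seed=s_sh)
        sid = f"SH{pair + 1:02d}"
        sham_logs[sid] = run_protocol(sh_subj, sham_plan, seed=s_sh,
                                      subject_id=sid,
                                      sham_logs=fb_logs[fid])
    return fb_logs, sham_logs


# ---------------------------------------------------------------- I/O ----

_SEGMENT_KEYS = ("times", "p", "f_raw", "f_capped", "f_displayed", "shown",
                 "l", "h", "alpha_p", "beta_p")


def write_session_log(log: SessionLog, path) -> None:
    """Persist a session log as JSON-lines (one header line, then one line
    per controller update; floats at full precision)."""
    def _clean(v):
        return None if isinstance(v, float) and np.isnan(v) else float(v)

    with open(path, "w") as fh:
        header = {
            "type": "header", "subject_id": log.subject_id,
            "session_index": log.session_index, "mode": log.mode,
            "seed": log.seed, "software_version": log.software_version,
            "plan": dataclasses.asdict(log.plan),
        }
        fh.write(json.dumps(header) + "\n")
        segments = ([("start_baseline", log.start_baseline)]
                    + [(f"block{i + 1}", b)
                       for i, b in enumerate(log.blocks)]
                    + [("end_baseline", log.end_baseline)])
        for name, seg in segments:
            for i in range(len(seg)):
                rec = {"type": "update", "segment": name, "i": i}
                for k in _SEGMENT_KEYS:
                    rec[k] = _clean(getattr(seg, k)[i])
                fh.write(json.dumps(rec) + "\n")


def read_session_log(path) -> SessionLog:
    """Read a JSON-lines session log; malformed lines raise ValueError
    naming the offending line number."""
    segments: dict[str, list[dict]] = {}
    header = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(
                    f"{path}: malformed JSON on line {lineno}: {exc}"
                ) from exc
            if rec.get("type") == "header":
                header = rec
            elif rec.get("type") == "update":
                for k in _SEGMENT_KEYS:
                    if rec.get(k) is None:
                        rec[k] = np.nan
                segments.setdefault(rec["segment"], []).append(rec)
            else:
                raise ValueError(
                    f"{path}: unknown record type on line {lineno}")
    if header is None:
        raise ValueError(f"{path}: missing header line")
    plan = SessionPlan(**header["plan"])
    block_names = sorted((n for n in segments if n.startswith("block")),
                         key=lambda n: int(n[5:]))
    return SessionLog(
        subject_id=header["subject_id"],
        session_index=header["session_index"], mode=header["mode"],
        plan=plan, seed=header["seed"],
        start_baseline=BlockLog.from_records(
            segments.get("start_baseline", [])),
        blocks=[BlockLog.from_records(segments[n]) for n in block_names],
        end_baseline=BlockLog.from_records(segments.get("end_baseline", [])),
        software_version=header.get("software_version", "unknown"))
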