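"""Event-related experiment designs: stimulus timing, labels and scan grid.

An :class:`ExperimentDesign` fixes everything the GLM and the simulator need
to know about an acquisition: one onset per stimulus event, the class label
and trial membership of each event, the stimulus duration, the repetition
time (TR) and the number of scans.  Two factories build designs shaped like
the classic sentence/picture and 8-category object-vision benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from voxelstab.errors import DesignError


@dataclass(frozen=True)
class ExperimentDesign:
    """Timing and labelling of an event-related acquisition.

    Parameters
    ----------
    n_trials, samples_per_trial
        Trial structure; ``n_trials * samples_per_trial`` equals the number
        of events before any trial is dropped.
    n_classes
        Number of stimulus categories.
    onsets
        Event onsets in seconds, strictly increasing, one per event.
    event_labels
        Integer class label in ``0..n_classes-1`` per event.
    trial_ids
        Trial index per event.
    stimulus_duration
        Presentation time of one stimulus, seconds.
    tr
        Repetition time (sampling interval of the scanner), seconds.
    n_scans
        Number of volumes acquired.
    """

    n_trials: int
    samples_per_trial: int
    n_classes: int
    onsets: np.ndarray
    event_labels: np.ndarray
    trial_ids: np.ndarray
    stimulus_duration: float
    tr: float
    n_scans: int

    def __post_init__(self):
        object.__setattr__(self, "onsets", np.asarray(self.onsets, dtype=float))
        object.__setattr__(
            self, "event_labels", np.asarray(self.event_labels, dtype=int)
        )
        object.__setattr__(self, "trial_ids", np.asarray(self.trial_ids, dtype=int))
        n_events = self.onsets.size
        if n_events != self.n_trials * self.samples_per_trial:
            raise DesignError(
                f"{n_events} onsets but n_trials*samples_per_trial = "
                f"{self.n_trials * self.samples_per_trial}"
            )
        if n_events and np.any(np.diff(self.onsets) <= 0):
            raise DesignError("onsets must be strictly increasing")
        if self.event_labels.size != n_events or self.trial_ids.size != n_events:
            raise DesignError("event_labels/trial_ids must match onset count")
        if n_events and (
            self.event_labels.min() < 0 or self.event_labels.max() >= self.n_classes
        ):
            raise DesignError("event labels outside 0..n_classes-1")
        if self.tr <= 0:
            raise DesignError("TR must be positive")
        if self.n_scans <= 0:
            raise DesignError("n_scans must be positive")

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)

    @property
    def scan_duration(self) -> float:
        return self.n_scans * self.tr

    def drop_trial(self, trial: int) -> "ExperimentDesign":
        """Return a copy with one trial's events removed (corrupted-run case)."""
        if trial < 0 or trial >= self.n_trials:
            raise DesignError(f"trial {trial} outside 0..{self.n_trials - 1}")
        keep = self.trial_ids != trial
        # renumber trials to stay contiguous
        new_ids = self.trial_ids[keep].copy()
        new_ids[new_ids > trial] -= 1
        return ExperimentDesign(
            n_trials=self.n_trials - 1,
            samples_per_trial=self.samples_per_trial,
            n_classes=self.n_classes,
            onsets=self.onsets[keep],
            event_labels=self.event_labels[keep],
            trial_ids=new_ids,
            stimulus_duration=self.stimulus_duration,
            tr=self.tr,
            n_scans=self.n_scans,
        )


def starplus_design(
    n_trials: int = 40,
    stimulus_duration: float = 4.0,
    rest: float = 8.0,
    tr: float = 0.5,
) -> ExperimentDesign:
    """Sentence/picture design: each trial shows two 4-s stimuli, one per class.

    Odd trials present the sentence (class 0) first, even trials the picture
    (class 1) first, mirroring the alternating order of the original
    experiment.  Trials are separated by a rest period.
    """
    onsets, labels, trials = [], [], []
    trial_len = 2 * stimulus_duration + rest
    for t in range(n_trials):
        first_semantic = t % 2 == 0
        for j in range(2):
            onsets.append(t * trial_len + j * stimulus_duration)
            labels.append(j if first_semantic else 1 - j)
            trials.append(t)
    n_scans = int(np.ceil((n_trials * trial_len + 24.0) / tr))
    return ExperimentDesign(
        n_trials=n_trials,
        samples_per_trial=2,
        n_classes=2,
        onsets=np.array(onsets),
        event_labels=np.array(labels),
        trial_ids=np.array(trials),
        stimulus_duration=stimulus_duration,
        tr=tr,
        n_scans=n_scans,
    )


def haxby_design(
    n_trials: int = 12,
    n_classes: int = 8,
    stimulus_duration: float = 0.5,
    isi: float = 1.5,
    rest: float = 12.0,
    tr: float = 2.5,
) -> ExperimentDesign:
    """Object-vision design: 12 trials x 8 category presentations.

    Within each trial the 8 categories are shown once each, 500 ms on with a
    1.5-s inter-stimulus interval (a ~16-s stimulation block per trial),
    trials separated by rest.  12 x 8 = 96 events in total.
    """
    onsets, labels, trials = [], [], []
    soa = stimulus_duration + isi
    trial_len = n_classes * soa + rest
    for t in range(n_trials):
        for c in range(n_classes):
            onsets.append(t * trial_len + c * soa)
            labels.append(c)
            trials.append(t)
    n_scans = int(np.ceil((n_trials * trial_len + 24.0) / tr))
    return ExperimentDesign(
        n_trials=n_trials,
        samples_per_trial=n_classes,
        n_classes=n_classes,
        onsets=np.array(onsets),
        event_labels=np.array(labels),
        trial_ids=np.array(trials),
        stimulus_duration=stimulus_duration,
        tr=tr,
        n_scans=n_scans,
    )
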