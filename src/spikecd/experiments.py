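"""Network architecture assembly and the functional tasks.

The supervised architecture splits the visible layer into sensory units
(pixels) and class-label units (several neurons per label, so no single
neuron has to drive the network at its saturation rate).  Pixels are
binarized to on-probabilities {1e-5, 0.98} and converted to clamp currents
by inverting the calibrated transfer curve.  Recognition reads out either
the most active class population in a sampling run or the label with the
lowest free energy; generation clamps a label population and reads back the
sensory units' firing probabilities.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .boltzmann import RBMParams, free_energy
from .calibration import TransferFit, inverse_transfer, rbm_to_network
from .dynamics import SpikeTrain, simulate
from .params import NeuronParams

__all__ = [
    "ArchitectureSpec",
    "ClampSpec",
    "PatternDataset",
    "P_ON",
    "P_OFF",
    "encode_image",
    "attach_label_clamp",
    "classify_by_rate",
    "classify_by_free_energy",
    "exact_label_posterior",
    "generate_from_label",
    "RescueMonitor",
    "synthetic_patterns",
    "read_idx",
    "write_idx",
    "UNDECIDED",
]

#: Binarized pixel on-probabilities: p <= 0.5 maps to P_OFF, p > 0.5 to P_ON.
P_OFF = 1e-5
P_ON = 0.98

#: Sentinel returned by the rate classifier when no class neuron spiked.
UNDECIDED = -1


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer layout: sensory + class-label visible units and hidden units."""

    n_vd: int                 # sensory visible units (pixels)
    n_labels: int             # number of class labels
    n_per_class: int = 4      # label neurons per class
    n_h: int = 500            # hidden units

    def __post_init__(self) -> None:
        if min(self.n_vd, self.n_labels, self.n_per_class, self.n_h) < 1:
            raise ValueError("all layer sizes must be positive")

    @property
    def n_vc(self) -> int:
        return self.n_labels * self.n_per_class

    @property
    def n_visible(self) -> int:
        return self.n_vd + self.n_vc

    def label_slice(self, label: int) -> slice:
        """Indices of the class neurons of ``label`` within the visible layer."""
        if not 0 <= label < self.n_labels:
            raise ValueError("label out of range")
        start = self.n_vd + label * self.n_per_class
        return slice(start, start + self.n_per_class)

    def label_vector(self, label: int) -> np.ndarray:
        """One-hot class-unit block: 1 for the label's neurons, 0 elsewhere."""
        v_c = np.zeros(self.n_vc)
        sl = self.label_slice(label)
        v_c[sl.start - self.n_vd:sl.stop - self.n_vd] = 1.0
        return v_c


@dataclass(frozen=True)
class ClampSpec:
    """Per-visible-neuron clamp currents over a time window."""

    currents: np.ndarray
    inhibited: frozenset
    window: tuple

    def __post_init__(self) -> None:
        if not self.window[0] < self.window[1]:
            raise ValueError("window start must precede end")


@dataclass(frozen=True)
class PatternDataset:
    """Binary-probability images with integer labels.

    ``images[k]`` holds per-pixel on-probabilities in {P_OFF, P_ON}.
    """

    images: np.ndarray
    labels: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        img = np.atleast_2d(np.asarray(self.images, dtype=float))
        lab = np.atleast_1d(np.asarray(self.labels, dtype=np.int64))
        if img.shape != (lab.size, self.n_pixels):
            raise ValueError("images must be (n_items, n_pixels)")
        if not np.all(np.isin(img, [P_OFF, P_ON])):
            raise ValueError(f"pixel values must be {{{P_OFF}, {P_ON}}}")
        object.__setattr__(self, "images", img)
        object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return self.labels.size

    def save_npz(self, path) -> None:
        np.savez(path, images=self.images, labels=self.labels,
                 n_pixels=self.n_pixels)

    @classmethod
    def load_npz(cls, path) -> "PatternDataset":
        with np.load(path) as z:
            return cls(images=z["images"], labels=z["labels"],
                       n_pixels=int(z["n_pixels"]))


def binarize(raw: np.ndarray) -> np.ndarray:
    """Map grayscale values in [0, 1] to on-probabilities {P_OFF, P_ON}."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0) or np.any(raw > 1):
        raise ValueError("raw pixel values must lie in [0, 1]")
    return np.where(raw > 0.5, P_ON, P_OFF)


def encode_image(raw: np.ndarray, fit: TransferFit) -> np.ndarray:
    """Binarize a grayscale image and convert to clamp currents."""
    return inverse_transfer(binarize(raw), fit)


def attach_label_clamp(arch: ArchitectureSpec, label, fit: TransferFit,
                       mode: str = "drive",
                       window: tuple = (0.0, np.inf)) -> ClampSpec:
    """Clamp currents for the class-label population(s).

    ``mode='drive'`` drives the label's neurons to high activity (P_ON
    current) and leaves the rest untouched; ``'inhibit_others'``
    additionally suppresses every other class neuron with the P_OFF
    current; ``'restrict_to_set'`` takes an iterable of labels that remain
    free while all other class neurons are suppressed.
    """
    currents = np.zeros(arch.n_visible)
    hi = inverse_transfer(P_ON, fit)
    lo = inverse_transfer(P_OFF, fit)
    inhibited: set[int] = set()
    if mode in ("drive", "inhibit_others"):
        sl = arch.label_slice(int(label))
        currents[sl] = hi
        if mode == "inhibit_others":
            for other in range(arch.n_labels):
                if other != int(label):
                    osl = arch.label_slice(other)
                    currents[osl] = lo
                    inhibited.update(range(osl.start, osl.stop))
    elif mode == "restrict_to_set":
        allowed = {int(x) for x in label}
        for other in range(arch.n_labels):
            if other not in allowed:
                osl = arch.label_slice(other)
                currents[osl] = lo
                inhibited.update(range(osl.start, osl.stop))
    else:
        raise ValueError("unknown clamp mode")
    return ClampSpec(currents=currents, inhibited=frozenset(inhibited),
                     window=window)


def classify_by_rate(spikes: SpikeTrain, arch: ArchitectureSpec,
                     window: float) -> int:
    """Label of the class population with the highest spike count.

    Counts spikes of each label population during the last ``window``
    seconds; ties resolve to the lowest label index.  Returns ``UNDECIDED``
    if no class neuron spiked at all.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t0 = max(0.0, spikes.t_end - window)
    sel = spikes.times >= t0
    counts = np.bincount(spikes.ids[sel], minlength=spikes.n_neurons)
    scores = np.array([counts[arch.label_slice(ell)].sum()
                       for ell in range(arch.n_labels)])
    if scores.sum() == 0:
        return UNDECIDED
    return int(np.argmax(scores))


def classify_by_free_energy(rbm: RBMParams, arch: ArchitectureSpec,
                            v_d: np.ndarray) -> int:
    """Label whose one-hot class configuration minimizes the free energy."""
    v_d = np.asarray(v_d, dtype=float)
    if v_d.size != arch.n_vd:
        raise ValueError("v_d must have n_vd entries")
    F = [free_energy(np.concatenate([v_d, arch.label_vector(ell)]), rbm)
         for ell in range(arch.n_labels)]
    return int(np.argmin(F))


def exact_label_posterior(rbm: RBMParams, arch: ArchitectureSpec,
                          v_d: np.ndarray) -> np.ndarray:
    """P(label | v_d) over one-hot class configurations, by enumeration.

    Marginalizes the hidden layer in closed form (via the free energy) and
    normalizes over labels; restricted to the one-hot class codes, it is the
    exact readout the free-energy classifier approximates with an argmin.
    """
    F = np.array([free_energy(np.concatenate(
        [np.asarray(v_d, float), arch.label_vector(ell)]), rbm)
        for ell in range(arch.n_labels)])
    w = np.exp(-(F - F.min()))
    return w / w.sum()


class RescueMonitor:
    """Hysteretic low-rate monitor driving a rescue excitation current.

    When a layer's population rate over the last window falls below the
    threshold (5 Hz by default) the monitor switches its excitation on; it
    stays on until the rate rises strictly above the threshold again.
    """

    def __init__(self, threshold_rate: float = 5.0, window: float = 50e-3):
        self.threshold_rate = threshold_rate
        self.window = window
        self.active = False

    def update(self, mean_rate: float) -> bool:
        if self.active:
            self.active = not (mean_rate > self.threshold_rate)
        else:
            self.active = mean_rate < self.threshold_rate
        return self.active


def generate_from_label(rbm: RBMParams, arch: ArchitectureSpec,
                        fit: TransferFit, label: int,
                        np_: NeuronParams | None = None,
                        t_run: float = 0.5, dt: float = 1e-4,
                        rng_seed: int = 0, equilibration: float | None = None,
                        rescue: bool = False,
                        rescue_current_scale: float = 1.0) -> np.ndarray:
    """Clamp a label population and read back the generated sensory image.

    The chosen label's class neurons are driven to high activity and all
    other class neurons strongly inhibited; the sensory units run freely.
    After discarding an equilibration interval (10 tau_r by default) the
    per-pixel on-probability is the firing rate times tau_r.  With
    ``rescue=True`` the run proceeds in windows and a hysteretic monitor
    injects an excitatory current into any layer whose rate drops below
    5 Hz, countering global bistability.
    """
    np_ = np_ or NeuronParams()
    equilibration = 10 * np_.tau_r if equilibration is None else equilibration
    if t_run <= equilibration:
        raise ValueError("t_run must exceed the equilibration interval")
    sp = rbm_to_network(rbm, fit)
    spec = attach_label_clamp(arch, label, fit, mode="inhibit_others")
    clamp = np.concatenate([spec.currents, np.zeros(arch.n_h)])
    if not rescue:
        st = simulate(np_, sp, clamp=clamp, t_end=t_run, dt=dt,
                      rng_seed=rng_seed)
        sel = st.times >= equilibration
        counts = np.bincount(st.ids[sel], minlength=sp.n_neurons)
        rates = counts / (t_run - equilibration)
    else:
        mon_v = RescueMonitor()
        mon_h = RescueMonitor()
        I_resc = rescue_current_scale * inverse_transfer(P_ON, fit)
        n = sp.n_neurons
        win = mon_v.window
        n_win = int(np.ceil(t_run / win))
        counts = np.zeros(n)
        kept_time = 0.0
        extra = np.zeros(n)
        for w in range(n_win):
            st = simulate(np_, sp, clamp=clamp + extra, t_end=win, dt=dt,
                          rng_seed=rng_seed + 31 * w)
            c = np.bincount(st.ids, minlength=n)
            t0 = w * win
            if t0 >= equilibration:
                counts += c
                kept_time += win
            rate_v = c[:arch.n_visible].sum() / (arch.n_visible * win)
            rate_h = c[arch.n_visible:].sum() / (arch.n_h * win)
            extra = np.zeros(n)
            if mon_v.update(rate_v):
                extra[:arch.n_visible] += I_resc
            if mon_h.update(rate_h):
                extra[arch.n_visible:] += I_resc
        rates = counts / max(kept_time, win)
    p_on = np.clip(rates[:arch.n_vd] * np_.tau_r, 0.0, 1.0)
    return p_on


def synthetic_patterns(n_classes: int, n_pixels: int,
                       noise_flip_prob: float = 0.0, n_items: int = 1,
                       rng_seed: int | np.random.Generator = 0) -> PatternDataset:
    """Noisy binary prototype patterns standing in for image data.

    Each class gets a disjoint block of on-pixels (orthogonal prototypes);
    items are prototypes with independent pixel flips at
    ``noise_flip_prob``, encoded to {P_OFF, P_ON}.
    """
    if n_classes > n_pixels:
        raise ValueError("need at least one pixel per class")
    if not 0 <= noise_flip_prob <= 1:
        raise ValueError("noise_flip_prob must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed) \
        if not isinstance(rng_seed, np.random.Generator) else rng_seed
    block = n_pixels // n_classes
    protos = np.zeros((n_classes, n_pixels))
    for c in range(n_classes):
        protos[c, c * block:(c + 1) * block] = 1.0
    labels = np.arange(n_items) % n_classes
    rng.shuffle(labels)
    imgs = protos[labels]
    flips = rng.random(imgs.shape) < noise_flip_prob
    imgs = np.abs(imgs - flips)
    return PatternDataset(images=np.where(imgs > 0.5, P_ON, P_OFF),
                          labels=labels, n_pixels=n_pixels)


# ---------------------------------------------------------------------------
# IDX (MNIST container format) reader/writer
# ---------------------------------------------------------------------------

_IDX_IMAGES = 0x00000803
_IDX_LABELS = 0x00000801


def _read_idx_array(path):
    with open(path, "rb") as fh:
        head = fh.read(4)
        if len(head) < 4:
            raise ValueError(f"{path}: truncated header at offset 0")
        magic, = struct.unpack(">I", head)
        if magic == _IDX_IMAGES:
            dims = struct.unpack(">III", fh.read(12))
            n, rows, cols = dims
            data = np.frombuffer(fh.read(), dtype=np.uint8)
            if data.size != n * rows * cols:
                raise ValueError(
                    f"{path}: expected {n * rows * cols} bytes after offset 16,"
                    f" found {data.size}")
            return data.reshape(n, rows * cols), magic
        if magic == _IDX_LABELS:
            n, = struct.unpack(">I", fh.read(4))
            data = np.frombuffer(fh.read(), dtype=np.uint8)
            if data.size != n:
                raise ValueError(
                    f"{path}: expected {n} bytes after offset 8, found {data.size}")
            return data, magic
        raise ValueError(f"{path}: bad IDX magic 0x{magic:08x} at offset 0")


def read_idx(images_path, labels_path=None) -> PatternDataset:
    """Read an IDX image file (and optional label file) into a dataset.

    Pixel bytes are scaled to [0, 1] and binarized to {P_OFF, P_ON}.
    Without a label file all labels are set to 0.
    """
    imgs, magic = _read_idx_array(images_path)
    if magic != _IDX_IMAGES:
        raise ValueError(f"{images_path} is not an IDX image file")
    images = binarize(imgs.astype(float) / 255.0)
    if labels_path is not None:
        labels, magic = _read_idx_array(labels_path)
        if magic != _IDX_LABELS:
            raise ValueError(f"{labels_path} is not an IDX label file")
        if labels.size != images.shape[0]:
            raise ValueError("label count does not match image count")
    else:
        labels = np.zeros(images.shape[0], dtype=np.int64)
    return PatternDataset(images=images, labels=labels.astype(np.int64),
                          n_pixels=images.shape[1])


def write_idx(images_path, labels_path, images: np.ndarray,
              labels: np.ndarray, rows: int, cols: int) -> None:
    """Write uint8 images/labels in IDX format (test fixtures, round trips)."""
    images = np.asarray(images, dtype=np.uint8)
    labels = np.asarray(labels, dtype=np.uint8)
    n = images.shape[0]
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">IIII", _IDX_IMAGES, n, rows, cols))
        fh.write(images.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">II", _IDX_LABELS, n))
        fh.write(labels.tobytes())
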