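"""Distance matrices, contact maps, and the structure-conditioned
autoregressive sequence model.

Distances are minimum all-atom inter-nucleotide distances in Angstroms
(hydrogens excluded). Contact maps come in two flavors: a symmetric
distance-cutoff map, and a per-row k-nearest-neighbor map (ties broken by
lower column index) which may be asymmetric and is symmetrized (union)
only for coverage and correlation analyses. Masked (unresolved) positions
carry an infinite sentinel and are excluded from neighbor selection.

The sequence model is a compact structured transformer: positions are
graph nodes attending to their k nearest structural neighbors, with edge
features built from sinusoidal relative-position encodings plus Gaussian
radial basis functions of the inter-nucleotide distance. Decoding is
autoregressive over alignment columns: when predicting column i, sequence
information is visible only at neighbor columns j < i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import AdamW, Tensor, masked_cross_entropy
from .sequence_io import AlignedFamily

GNN_ALPHABET = "AUCG-X"
_GNN_IDX = {c: i for i, c in enumerate(GNN_ALPHABET)}

# common post-transcriptional modifications seen in rRNA structures
_MODIFIED_PARENT = {
    "PSU": "U", "5MU": "U", "4SU": "U", "H2U": "U", "3MU": "U", "UR3": "U",
    "OMU": "U", "5MC": "C", "OMC": "C", "4OC": "C", "1MA": "A", "MA6": "A",
    "2MA": "A", "6MZ": "A", "OMA": "A", "2MG": "G", "7MG": "G", "M2G": "G",
    "OMG": "G", "1MG": "G", "G7M": "G",
}


@dataclass
class DistanceMatrix:
    """Symmetric inter-nucleotide distance matrix (A) with a validity mask.

    Masked positions (mask False) carry +inf off-diagonal sentinels.
    """

    D: np.ndarray
    labels: list[str]
    mask: np.ndarray

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.D.shape[0]
        if self.D.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if len(self.labels) != n or self.mask.shape != (n,):
            raise ValueError("labels/mask length must match matrix size")

    @property
    def n(self) -> int:
        return self.D.shape[0]


@dataclass
class ContactMap:
    M: np.ndarray
    method: str  # "cutoff" or "knn"
    param: float

    @property
    def support(self) -> np.ndarray:
        return self.M != 0


def load_chain_residues(path, chain_name: str):
    """Read a PDB/mmCIF file with gemmi; return (labels, atom coordinate
    arrays, canonical sequence) for the nucleotides of one chain.

    Modified nucleotides are mapped to their parent A/C/G/U; hydrogens are
    dropped; residues with no heavy atoms are masked downstream.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chain = model.find_chain(chain_name)
    if chain is None:
        raise ValueError(f"chain {chain_name!r} not found in {path}")
    labels, coords, seq = [], [], []
    for res in chain:
        letter = _MODIFIED_PARENT.get(res.name.strip())
        if letter is None:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_nucleic_acid():
                continue
            letter = info.one_letter_code.upper()
            if letter == "T":
                letter = "U"
        if letter not in "ACGU":
            letter = "N"
        xyz = np.array(
            [[a.pos.x, a.pos.y, a.pos.z] for a in res if not a.is_hydrogen()]
        )
        labels.append(f"{res.seqid.num}{res.name.strip()}")
        coords.append(xyz)
        seq.append(letter)
    if len(coords) < 2:
        raise ValueError(f"chain {chain_name!r} has fewer than 2 nucleotides")
    return labels, coords, "".join(seq)


def min_atom_distance_matrix(
    residue_coords: list[np.ndarray], labels: list[str] | None = None
) -> DistanceMatrix:
    """Minimum Euclidean distance between any two heavy atoms of each
    residue pair. Residues with no atoms are masked (+inf sentinels)."""
    from scipy.spatial.distance import cdist

    n = len(residue_coords)
    if n < 2:
        raise ValueError("need at least 2 residues")
    labels = labels or [str(i + 1) for i in range(n)]
    mask = np.array([len(c) > 0 for c in residue_coords], dtype=bool)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        if not mask[i]:
            continue
        for j in range(i + 1, n):
            if not mask[j]:
                continue
            d = cdist(residue_coords[i], residue_coords[j]).min()
            D[i, j] = D[j, i] = d
    return DistanceMatrix(D=D, labels=labels, mask=mask)


def _pairwise_align(a: str, b: str):
    """Global alignment of a (possibly gappy subsequence) against b."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    return aln


def align_distance_matrix_to_msa(
    dm: DistanceMatrix,
    pdb_sequence: str,
    full_sequence: str,
    family: AlignedFamily,
    ref_row_id: str,
    struct_row_id: str | None = None,
) -> tuple[DistanceMatrix, "np.ndarray"]:
    """Lift a structure-derived distance matrix into projected-MSA coordinates.

    Three steps: (1) align the structure's resolved sequence to its
    full-length sequence and insert sentinel rows/columns at unresolved
    positions; (2) spread the matrix over the MSA columns using the
    structure's row in the family; (3) drop columns where the reference
    row is gapped, mirroring the family projection. Returns the matrix
    (width = projected family width) and the projected-column index of
    each original residue (-1 if dropped).
    """
    from .sequence_io import project_to_reference

    struct_row_id = struct_row_id or ref_row_id
    if pdb_sequence.replace("N", "") == "":
        raise ValueError("empty structure sequence")

    # step 1: full-sequence coordinates with sentinels at unresolved residues
    aln = _pairwise_align(pdb_sequence, full_sequence)
    pdb_to_full = np.full(len(pdb_sequence), -1, dtype=int)
    for (ps, pe), (fs, fe) in zip(*aln.aligned):
        pdb_to_full[ps:pe] = np.arange(fs, fe)
    if (pdb_to_full < 0).all():
        raise ValueError("structure sequence could not be aligned to the full sequence")
    nf = len(full_sequence)
    D1 = np.full((nf, nf), np.inf)
    np.fill_diagonal(D1, 0.0)
    mask1 = np.zeros(nf, dtype=bool)
    resolved = pdb_to_full >= 0
    idx = pdb_to_full[resolved]
    mask1[idx] = dm.mask[resolved]
    D1[np.ix_(idx, idx)] = dm.D[np.ix_(resolved, resolved)]

    # step 2: MSA coordinates via the structure's own row
    struct_row = family.row(struct_row_id)
    res_cols = [c for c, ch in enumerate(struct_row) if ch != "-"]
    if len(res_cols) != nf:
        raise ValueError(
            f"row {struct_row_id!r} has {len(res_cols)} residues but the full "
            f"sequence has {nf}"
        )
    W = family.n_columns
    D2 = np.full((W, W), np.inf)
    np.fill_diagonal(D2, 0.0)
    mask2 = np.zeros(W, dtype=bool)
    cols = np.array(res_cols)
    mask2[cols] = mask1
    D2[np.ix_(cols, cols)] = D1

    # step 3: keep only reference-row columns
    _, column_map = project_to_reference(family, ref_row_id)
    keep = np.array(sorted(column_map), dtype=int)
    D3 = D2[np.ix_(keep, keep)]
    mask3 = mask2[keep]
    labels = [str(c) for c in keep]
    # projected index of each original residue
    full_to_proj = np.full(nf, -1, dtype=int)
    for k, c in enumerate(cols):
        if int(c) in column_map:
            full_to_proj[k] = column_map[int(c)]
    return DistanceMatrix(D=D3, labels=labels, mask=mask3), full_to_proj


def contact_map(dm: DistanceMatrix, method: str, value: float) -> ContactMap:
    if method == "cutoff":
        return contact_map_cutoff(dm, value)
    if method == "knn":
        return contact_map_knn(dm, int(value))
    raise ValueError(f"unknown contact map method {method!r}")


def contact_map_cutoff(dm: DistanceMatrix, d: float) -> ContactMap:
    """Symmetric map: 1 where distance < d, zero diagonal and masked lines."""
    M = (dm.D < d).astype(np.uint8)
    np.fill_diagonal(M, 0)
    M[~dm.mask, :] = 0
    M[:, ~dm.mask] = 0
    return ContactMap(M=M, method="cutoff", param=float(d))


def knn_neighbors(dm: DistanceMatrix, k: int) -> np.ndarray:
    """Per-row indices of the k nearest unmasked residues (self excluded),
    distance ties broken by lower index. Masked rows give -1 everywhere."""
    n = dm.n
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the residue count {n}")
    nbr = np.full((n, k), -1, dtype=int)
    for i in range(n):
        if not dm.mask[i]:
            continue
        d = dm.D[i].copy()
        d[i] = np.inf
        d[~dm.mask] = np.inf
        finite = np.flatnonzero(np.isfinite(d))
        if len(finite) == 0:
            continue
        order = finite[np.lexsort((finite, d[finite]))]
        take = order[:k]
        nbr[i, : len(take)] = take
    return nbr


def contact_map_knn(dm: DistanceMatrix, k: int) -> ContactMap:
    nbr = knn_neighbors(dm, k)
    M = np.zeros((dm.n, dm.n), dtype=np.uint8)
    for i in range(dm.n):
        cols = nbr[i][nbr[i] >= 0]
        M[i, cols] = 1
    return ContactMap(M=M, method="knn", param=float(k))


def write_edge_list(path, cm: ContactMap, dm: DistanceMatrix | None = None) -> None:
    """Export a contact map as a TSV edge list (1-based positions)."""
    with open(str(path), "w") as fh:
        fh.write("i\tj\tdistance_angstrom\n" if dm is not None else "i\tj\n")
        for i, j in zip(*np.nonzero(cm.M)):
            if dm is not None:
                fh.write(f"{i + 1}\t{j + 1}\t{dm.D[i, j]:.3f}\n")
            else:
                fh.write(f"{i + 1}\t{j + 1}\n")


def symmetrized(cm: ContactMap) -> ContactMap:
    M = ((cm.M + cm.M.T) > 0).astype(np.uint8)
    return ContactMap(M=M, method=cm.method + "_sym", param=cm.param)


def structural_correlation(a: ContactMap, b: ContactMap) -> float:
    """Corr(A,B) = sum(A*B) / sqrt(sum(A^2) * sum(B^2)).

    Returns NaN when either map is all-zero (undefined).
    """
    A = a.M.astype(float)
    B = b.M.astype(float)
    if A.shape != B.shape:
        raise ValueError("contact maps must have the same dimensions")
    na = (A * A).sum()
    nb = (B * B).sum()
    if na == 0 or nb == 0:
        return float("nan")
    return float((A * B).sum() / np.sqrt(na * nb))


def min_uncovered_distance(dm: DistanceMatrix, k: int) -> float:
    """Smallest finite distance missing from the symmetrized k-NN map;
    +inf when every finite pair is covered."""
    cov = symmetrized(contact_map_knn(dm, k)).M.astype(bool)
    n = dm.n
    iu = np.triu_indices(n, 1)
    finite = np.isfinite(dm.D[iu]) & dm.mask[iu[0]] & dm.mask[iu[1]]
    uncovered = finite & ~cov[iu]
    if not uncovered.any():
        return float("inf")
    return float(dm.D[iu][uncovered].min())


def random_degree_matched_neighbors(
    nbr: np.ndarray, rng: np.random.Generator | int
) -> np.ndarray:
    """Control graph: same per-row neighbor count, random partners."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    n, k = nbr.shape
    out = np.full_like(nbr, -1)
    for i in range(n):
        deg = int((nbr[i] >= 0).sum())
        if deg == 0:
            continue
        choices = np.delete(np.arange(n), i)
        out[i, :deg] = rng.choice(choices, size=deg, replace=False)
    return out


# ---------------------------------------------------------------------------
# graph featurization and the structured sequence model
# ---------------------------------------------------------------------------


@dataclass
class GNNConfig:
    k: int = 50
    hidden_dim: int = 128
    n_encoder_layers: int = 1
    n_decoder_layers: int = 3
    rbf_count: int = 16
    rbf_min: float = 0.0
    rbf_max: float = 20.0
    abs_pos_features: int = 16
    relpos_features: int = 16
    dropout: float = 0.10
    label_smoothing: float = 0.10

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.relpos_features % 2:
            raise ValueError("relpos_features must be even")


@dataclass
class GraphFeatures:
    neighbor_idx: np.ndarray  # (W, k) int, -1 for absent
    edge_feat: np.ndarray  # (W, k, relpos + rbf) float32
    causal: np.ndarray  # (W, k) bool: neighbor index < node index
    valid: np.ndarray  # (W, k) bool: neighbor present
    n_nodes: int


def rbf_expand(d: np.ndarray, cfg: GNNConfig) -> np.ndarray:
    """Gaussian radial basis activations with centers evenly spaced on
    [rbf_min, rbf_max] and width equal to the center spacing."""
    centers = np.linspace(cfg.rbf_min, cfg.rbf_max, cfg.rbf_count)
    width = centers[1] - centers[0]
    d = np.where(np.isfinite(d), d, cfg.rbf_max * 2.0)
    return np.exp(-(((d[..., None] - centers) / width) ** 2)).astype(np.float32)


def _sinusoid(rel: np.ndarray, dim: int) -> np.ndarray:
    half = dim // 2
    freqs = 1.0 / (10000.0 ** (np.arange(half) / max(half, 1)))
    ang = rel[..., None] * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=-1).astype(np.float32)


def build_graph_features(
    dm: DistanceMatrix, cfg: GNNConfig, neighbor_idx: np.ndarray | None = None
) -> GraphFeatures:
    """Per-edge features for each node's k nearest neighbors.

    `neighbor_idx` can override the k-NN selection (e.g. with a
    degree-matched random control graph)."""
    nbr = knn_neighbors(dm, cfg.k) if neighbor_idx is None else neighbor_idx
    W = dm.n
    valid = nbr >= 0
    safe = np.where(valid, nbr, 0)
    rel = (safe - np.arange(W)[:, None]).astype(float)
    dist = dm.D[np.arange(W)[:, None], safe]
    edge = np.concatenate(
        [_sinusoid(rel, cfg.relpos_features), rbf_expand(dist, cfg)], axis=-1
    )
    edge[~valid] = 0.0
    causal = valid & (safe < np.arange(W)[:, None])
    return GraphFeatures(
        neighbor_idx=safe, edge_feat=edge, causal=causal, valid=valid, n_nodes=W
    )


def _linear(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    scale = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-scale, scale, size=(fan_in, fan_out)), requires_grad=True)


class StructuredSequenceModel:
    """Autoregressive model over alignment columns conditioned on a fixed
    structural neighbor graph (one encoder + several decoder layers)."""

    def __init__(self, graph: GraphFeatures, cfg: GNNConfig, rng_seed: int = 0):
        self.graph = graph
        self.cfg = cfg
        self.rng_seed = rng_seed
        rng = np.random.default_rng(rng_seed)
        h = cfg.hidden_dim
        e_in = graph.edge_feat.shape[-1]
        A = len(GNN_ALPHABET)
        p: dict[str, Tensor] = {}
        p["abs_pos"] = Tensor(rng.normal(0, 0.5, size=(graph.n_nodes, cfg.abs_pos_features)),
                              requires_grad=True)
        p["node_in"] = _linear(rng, cfg.abs_pos_features, h)
        p["edge_in"] = _linear(rng, e_in, h)
        p["seq_emb"] = Tensor(rng.normal(0, 0.5, size=(A, h)), requires_grad=True)
        for li in range(cfg.n_encoder_layers + cfg.n_decoder_layers):
            is_dec = li >= cfg.n_encoder_layers
            p[f"l{li}_q"] = _linear(rng, h, h)
            p[f"l{li}_kh"] = _linear(rng, h, h)
            p[f"l{li}_ke"] = _linear(rng, h, h)
            p[f"l{li}_vh"] = _linear(rng, h, h)
            p[f"l{li}_ve"] = _linear(rng, h, h)
            if is_dec:
                p[f"l{li}_ks"] = _linear(rng, h, h)
                p[f"l{li}_vs"] = _linear(rng, h, h)
            p[f"l{li}_o"] = _linear(rng, h, h)
            p[f"l{li}_g1"] = Tensor(np.ones(h), requires_grad=True)
            p[f"l{li}_f1"] = _linear(rng, h, 4 * h)
            p[f"l{li}_f2"] = _linear(rng, 4 * h, h)
            p[f"l{li}_g2"] = Tensor(np.ones(h), requires_grad=True)
        p["out_g"] = Tensor(np.ones(h), requires_grad=True)
        p["out"] = _linear(rng, h, A)
        self.params = p

    # -- helpers ---------------------------------------------------------------
    @staticmethod
    def _rms(x: Tensor, g: Tensor) -> Tensor:
        scale = ((x * x).mean(axis=-1, keepdims=True) + 1e-6) ** -0.5
        return x * scale * g

    def _attend(self, li: int, hB: Tensor, seq_emb: Tensor | None,
                drop_rng: np.random.Generator | None) -> Tensor:
        """One neighborhood-attention + FFN block. hB: (B, W, h)."""
        g = self.graph
        p = self.params
        cfg = self.cfg
        B = hB.shape[0]
        if g.neighbor_idx.shape[1] == 0:
            attn_out = Tensor(np.zeros_like(hB.data))
        else:
            hn = self._rms(hB, p[f"l{li}_g1"])
            # gather neighbor states: (B, W, k, h); edge terms broadcast over B
            nbr_h = hn[:, g.neighbor_idx]
            kk = nbr_h @ p[f"l{li}_kh"] + self._edge_h @ p[f"l{li}_ke"]
            vv = nbr_h @ p[f"l{li}_vh"] + self._edge_h @ p[f"l{li}_ve"]
            if seq_emb is not None:
                causal = Tensor(g.causal[None, :, :, None].astype(np.float32))
                nbr_s = seq_emb[:, g.neighbor_idx] * causal
                kk = kk + nbr_s @ p[f"l{li}_ks"]
                vv = vv + nbr_s @ p[f"l{li}_vs"]
            q = hn @ p[f"l{li}_q"]  # (B, W, h)
            scale = 1.0 / np.sqrt(cfg.hidden_dim)
            scores = (q.reshape(B, g.n_nodes, 1, cfg.hidden_dim) * kk).sum(axis=-1) * scale
            neg = np.where(g.valid, 0.0, -1e9).astype(np.float32)
            scores = scores + Tensor(neg[None])
            w = scores.softmax(axis=-1)
            if drop_rng is not None and cfg.dropout > 0:
                keep = (drop_rng.random(w.shape) >= cfg.dropout) / (1 - cfg.dropout)
                w = w * Tensor(keep.astype(np.float32))
            ctx = (w.reshape(B, g.n_nodes, -1, 1) * vv).sum(axis=2)
            attn_out = ctx @ p[f"l{li}_o"]
        hB = hB + attn_out
        hn = self._rms(hB, p[f"l{li}_g2"])
        ff = (hn @ p[f"l{li}_f1"]).gelu() @ p[f"l{li}_f2"]
        if drop_rng is not None and cfg.dropout > 0:
            keep = (drop_rng.random(ff.shape) >= cfg.dropout) / (1 - cfg.dropout)
            ff = ff * Tensor(keep.astype(np.float32))
        return hB + ff

    def forward(self, rows: np.ndarray, train: bool = False,
                drop_rng: np.random.Generator | None = None) -> Tensor:
        """rows: (B, W) int alphabet indices; returns logits (B, W, A)."""
        g = self.graph
        p = self.params
        B, W = rows.shape
        if W != g.n_nodes:
            raise ValueError(f"family width {W} != graph size {g.n_nodes}")
        rng = drop_rng if train else None
        self._edge_h = Tensor(g.edge_feat) @ p["edge_in"]  # (W, k, h)
        node = (p["abs_pos"] @ p["node_in"]).reshape(1, W, -1)
        hB = node + Tensor(np.zeros((B, W, self.cfg.hidden_dim), dtype=np.float32))
        seq_emb = p["seq_emb"][rows]  # (B, W, h)
        li = 0
        for _ in range(self.cfg.n_encoder_layers):
            hB = self._attend(li, hB, None, rng)
            li += 1
        for _ in range(self.cfg.n_decoder_layers):
            hB = self._attend(li, hB, seq_emb, rng)
            li += 1
        hB = self._rms(hB, p["out_g"])
        return hB @ p["out"]

    def loss(self, rows: np.ndarray, train: bool = False,
             drop_rng: np.random.Generator | None = None) -> Tensor:
        logits = self.forward(rows, train=train, drop_rng=drop_rng)
        B, W, A = logits.shape
        flat = logits.reshape(B * W, A)
        mask = np.broadcast_to(self.graph_mask(), (B, W)).reshape(-1)
        smoothing = self.cfg.label_smoothing if train else 0.0
        return masked_cross_entropy(flat, rows.reshape(-1), mask, smoothing)

    def graph_mask(self) -> np.ndarray:
        """Columns included in the loss (structured positions only)."""
        if not hasattr(self, "_col_mask"):
            self._col_mask = np.ones(self.graph.n_nodes, dtype=bool)
        return self._col_mask

    def set_column_mask(self, mask: np.ndarray) -> None:
        self._col_mask = np.asarray(mask, dtype=bool)

    def clone(self) -> "StructuredSequenceModel":
        other = StructuredSequenceModel(self.graph, self.cfg, self.rng_seed)
        for k, v in self.params.items():
            other.params[k].data = v.data.copy()
        return other


def encode_rows(family: AlignedFamily) -> np.ndarray:
    out = np.zeros((family.n_rows, family.n_columns), dtype=np.int64)
    for r, (_, seq) in enumerate(family.rows):
        out[r] = [_GNN_IDX.get(c, _GNN_IDX["X"]) for c in seq.replace("N", "X")]
    return out


@dataclass
class GNNTrainReport:
    history: list[dict] = field(default_factory=list)
    best_iteration: int = -1
    best_val_nll: float = float("inf")

    @property
    def best_val_perplexity(self) -> float:
        return float(np.exp(self.best_val_nll))


def gnn_evaluate(model: StructuredSequenceModel, rows: np.ndarray,
                 batch_size: int = 64) -> float:
    """Mean per-column NLL (no dropout, no smoothing)."""
    total, count = 0.0, 0
    ncols = int(model.graph_mask().sum())
    for s in range(0, len(rows), batch_size):
        batch = rows[s : s + batch_size]
        loss = model.loss(batch, train=False)
        total += float(loss.data) * len(batch) * ncols
        count += len(batch) * ncols
    return total / max(count, 1)


def gnn_train(
    model: StructuredSequenceModel,
    train_rows: np.ndarray,
    val_rows: np.ndarray,
    max_iters: int = 2000,
    batch_size: int = 16,
    lr: float = 1e-3,
    eval_interval: int = 100,
    early_stop_patience: int = 5,
    rng_seed: int = 0,
) -> tuple[StructuredSequenceModel, GNNTrainReport]:
    if len(train_rows) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(rng_seed)
    drop_rng = np.random.default_rng(rng.integers(2**31))
    opt = AdamW(model.params, lr=lr, betas=(0.9, 0.999), weight_decay=0.01)
    report = GNNTrainReport()
    best_params = {k: v.data.copy() for k, v in model.params.items()}
    stall = 0
    for it in range(1, max_iters + 1):
        idx = rng.integers(0, len(train_rows), size=batch_size)
        loss = model.loss(train_rows[idx], train=True, drop_rng=drop_rng)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if it % eval_interval == 0 or it == max_iters:
            val_nll = gnn_evaluate(model, val_rows)
            report.history.append(
                {"iteration": it, "train_loss": float(loss.data),
                 "val_nll": val_nll, "val_perplexity": float(np.exp(val_nll))}
            )
            if val_nll < report.best_val_nll - 1e-4:
                report.best_val_nll = val_nll
                report.best_iteration = it
                best_params = {k: v.data.copy() for k, v in model.params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= early_stop_patience:
                    break
    for k, v in model.params.items():
        v.data = best_params[k]
    if report.best_val_nll == float("inf"):
        report.best_val_nll = gnn_evaluate(model, val_rows)
    return model, report


def gnn_log_probability(model: StructuredSequenceModel, row: np.ndarray) -> float:
    """Sum of log p(column | structure, previous neighbor columns)."""
    logits = model.forward(row[None], train=False).data[0]
    z = logits - logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    mask = model.graph_mask()
    return float(logp[np.arange(len(row)), row][mask].sum())


def gnn_generate(
    model: StructuredSequenceModel,
    seed_columns: np.ndarray,
    n_sequences: int,
    temperature: float = 0.5,
    rng_seed: int = 0,
) -> np.ndarray:
    """Sample alignment rows column-by-column after a seeded prefix."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    rng = np.random.default_rng(rng_seed)
    W = model.graph.n_nodes
    s = len(seed_columns)
    rows = np.full((n_sequences, W), _GNN_IDX["X"], dtype=np.int64)
    rows[:, :s] = seed_columns
    for i in range(s, W):
        logits = model.forward(rows, train=False).data[:, i, :].astype(np.float64)
        logits /= temperature
        logits -= logits.max(axis=-1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=-1, keepdims=True)
        u = rng.random((n_sequences, 1))
        rows[:, i] = (probs.cumsum(axis=-1) > u).argmax(axis=-1)
    return rows


def decode_rows(rows: np.ndarray) -> list[str]:
    return ["".join(GNN_ALPHABET[i] for i in r) for r in rows]
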