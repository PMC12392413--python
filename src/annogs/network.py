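"""Annotation-structured neural network for phenotype prediction.

The model is a feed-forward network whose first layers are wired by biology:

* input: the genotype vector (one node per SNP, dosage coded 0/1/2);
* internal layer 1 ("element" layer): nodes assigned to cis-regulatory
  elements (and, for coding SNPs, to gene proxies); the input->H1 weight
  matrix is masked so a SNP only feeds nodes of the element/gene it is
  assigned to.  At annotation level >= 2, per-SNP functional-impact features
  (dosage-weighted allelic chromatin-accessibility deltas for noncoding SNPs,
  RNA minimum-free-energy deltas for coding SNPs) are injected in parallel,
  under the same mask;
* internal layer 2 ("gene" layer): nodes assigned to genes; the H1->H2 mask
  follows element->gene links.  At level >= 3, per-term gene-function
  features are injected;
* internal layer 3: dense; at level 4, per-metaterm regulatory-module
  features are injected;
* remaining internal layers: dense hidden layers; the output layer is a
  single linear node producing the predicted phenotype.

Internal layer widths are ``base_unit * unit_ratio[i]``.  Because every
masked node carries exactly one biological entity, trained weights can be
traced backwards to metaterms, terms, genes, elements and SNPs (see
:mod:`annogs.interpret`).

Training is full-batch gradient descent with momentum, batch normalization
and dropout on the internal layers, and an L1/L2 weight penalty with the
fixed binding coefficient 1e-5.  All randomness (initialization, dropout)
flows from a single seed, so a given (data, spec, seed) triple yields a
bit-identical loss trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AnnotationBundle, GenotypeMatrix, ImpactScores, PhenotypeVector

__all__ = [
    "NetworkSpec",
    "AnnotationNetwork",
    "TrainedNetwork",
    "build_network",
    "compute_loss",
    "train_network",
    "optimal_step",
    "predict",
]

PENALTY_COEFFICIENT = 1e-5
_BN_EPS = 1e-5

LEVEL_NAMES = {1: "genotype", 2: "snp_annotation", 3: "function", 4: "network"}


@dataclass
class NetworkSpec:
    """Hyperparameters and architecture of the annotation network."""

    annotation_level: int = 4
    base_unit: int = 110
    unit_ratio: tuple[int, ...] = (1, 2, 4, 5, 6, 7)
    activation: str = "relu"  # relu | tanh | linear
    learning_rate: float = 0.1
    momentum: float = 0.9
    bn_momentum: float = 0.9
    dropout_rate: float = 0.1
    reg_norm: str = "L2"  # L1 | L2
    reg_rate: float = 0.01
    penalty_coefficient: float = PENALTY_COEFFICIENT
    use_batch_norm: bool = True

    def __post_init__(self) -> None:
        if self.annotation_level not in LEVEL_NAMES:
            raise ValueError("annotation_level must be in {1,2,3,4}")
        if self.base_unit < 1 or any(r < 1 for r in self.unit_ratio):
            raise ValueError("base_unit and unit_ratio entries must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.reg_rate < 0:
            raise ValueError("reg_rate must be >= 0")
        if self.reg_norm not in ("L1", "L2"):
            raise ValueError("reg_norm must be L1 or L2")
        if self.activation not in ("relu", "tanh", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")
        self.unit_ratio = tuple(int(r) for r in self.unit_ratio)

    @property
    def internal_widths(self) -> tuple[int, ...]:
        return tuple(self.base_unit * r for r in self.unit_ratio)

    @property
    def depth(self) -> int:
        return len(self.unit_ratio)


def compute_loss(
    y_real: np.ndarray,
    y_pred: np.ndarray,
    weights: list[np.ndarray],
    reg_norm: str = "L2",
    reg_rate: float = 0.0,
    penalty_coefficient: float = PENALTY_COEFFICIENT,
) -> float:
    """Mean squared error plus the bound weight penalty.

    ``loss = (1/n) sum (y - yhat)^2 + c * alpha * sum_i |w_i|^k`` with
    ``k = 1`` (L1) or ``2`` (L2) over every entry of every weight tensor.
    """
    y_real = np.asarray(y_real, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_real.shape != y_pred.shape:
        raise ValueError("y_real and y_pred must have equal length")
    n = y_real.size
    if n == 0:
        raise ValueError("loss undefined for n = 0")
    mse = float(np.mean((y_real - y_pred) ** 2))
    k = 1 if reg_norm == "L1" else 2
    pen = sum(float(np.sum(np.abs(w) ** k)) for w in weights)
    return mse + penalty_coefficient * reg_rate * pen


def optimal_step(loss_trace) -> int:
    """First 1-based step attaining the global minimum of the loss trace.

    This is the step after which the minimum never decreases again (the
    training-plateau rule used to pick the number of steps for final CV).
    """
    trace = np.asarray(loss_trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty loss trace")
    return int(np.argmin(trace)) + 1


def _activation(name):
    if name == "relu":
        return (lambda z: np.maximum(z, 0.0), lambda z, h: (z > 0).astype(float))
    if name == "tanh":
        return (np.tanh, lambda z, h: 1.0 - h**2)
    return (lambda z: z, lambda z, h: np.ones_like(z))


class AnnotationNetwork:
    """A built (and possibly trained) annotation-structured network."""

    def __init__(
        self,
        spec: NetworkSpec,
        bundle: AnnotationBundle,
        impacts: ImpactScores,
        snp_ids: list[str],
        snp_categories: list[str],
    ):
        self.spec = spec
        self.snp_ids = list(snp_ids)
        self.loss_trace: np.ndarray | None = None
        self._trained = False
        p = len(snp_ids)

        # --- fixed feature machinery (allelic deltas and cascades) ----------
        delta = np.zeros(p)
        for j, (sid, cat) in enumerate(zip(snp_ids, snp_categories)):
            table = impacts.noncoding_access if cat == "noncoding" else impacts.coding_mfe
            if sid in table.index:
                delta[j] = table.at[sid, "alt_score"] - table.at[sid, "ref_score"]
        self._delta = delta
        self._noncoding = np.array([c == "noncoding" for c in snp_categories])

        genes = bundle.genes
        g_index = {g: i for i, g in enumerate(genes)}
        incidence = np.zeros((p, len(genes)))
        for j, sid in enumerate(snp_ids):
            g = bundle.snp_to_gene.get(sid)
            if g is not None:
                incidence[j, g_index[g]] = 1.0
        counts = incidence.sum(axis=0)
        counts[counts == 0] = 1.0
        self._snp_gene = incidence / counts  # column-normalized: per-gene mean
        if len(bundle.gene_term_scores):
            self._gene_term = bundle.gene_term_scores.reindex(genes).fillna(0.0).to_numpy()
        else:
            self._gene_term = np.zeros((len(genes), 0))
        self._term_meta = bundle.term_metaterm_weights.to_numpy(dtype=float) if len(
            bundle.term_metaterm_weights
        ) else np.zeros((self._gene_term.shape[1], 0))
        self._inj_stats: dict[int, tuple[np.ndarray, np.ndarray]] = {}

        # --- entity assignment and masks ------------------------------------
        elements = bundle.elements
        coding_genes = sorted(
            {bundle.snp_to_gene[s] for s, c in zip(snp_ids, snp_categories)
             if c == "coding" and s in bundle.snp_to_gene},
            key=lambda g: g_index[g],
        )
        e1_entities = [("element", e) for e in elements] + [
            ("coding_gene", g) for g in coding_genes
        ]
        widths = spec.internal_widths
        self.h1_entities = [e1_entities[k % len(e1_entities)] for k in range(widths[0])] \
            if e1_entities else [("none", "")] * widths[0]
        self.h2_entities = (
            [("gene", genes[k % len(genes)]) for k in range(widths[1])]
            if len(widths) > 1 and genes
            else []
        )

        snp_entity = {}
        for sid, cat in zip(snp_ids, snp_categories):
            if cat == "noncoding" and sid in bundle.snp_to_element:
                snp_entity[sid] = ("element", bundle.snp_to_element[sid])
            elif cat == "coding" and sid in bundle.snp_to_gene:
                snp_entity[sid] = ("coding_gene", bundle.snp_to_gene[sid])

        mask1_geno = np.zeros((p, widths[0]))
        for j, sid in enumerate(snp_ids):
            ent = snp_entity.get(sid)
            if ent is None:
                continue
            for k, nk in enumerate(self.h1_entities):
                if nk == ent:
                    mask1_geno[j, k] = 1.0
        self._mask1_geno = mask1_geno

        mask2 = None
        if self.h2_entities:
            e_to_g = {}
            for e, gs in bundle.element_to_gene.items():
                e_to_g[("element", e)] = set(gs)
            for g in coding_genes:
                e_to_g.setdefault(("coding_gene", g), set()).add(g)
            mask2 = np.zeros((widths[0], widths[1]))
            for k1, ent1 in enumerate(self.h1_entities):
                targets = e_to_g.get(ent1, set())
                for k2, (_, g) in enumerate(self.h2_entities):
                    if g in targets:
                        mask2[k1, k2] = 1.0
        self._mask2_h1 = mask2

        # --- layer input layout ---------------------------------------------
        level = spec.annotation_level
        self.n_terms = self._gene_term.shape[1]
        self.n_meta = self._term_meta.shape[1]
        self._inject = {
            0: p if level >= 2 else 0,
            1: self.n_terms if (level >= 3 and len(widths) > 1) else 0,
            2: self.n_meta if (level >= 4 and len(widths) > 2) else 0,
        }

        dims = []
        prev = p
        for l, w in enumerate(widths):
            dims.append((prev + self._inject.get(l, 0), w))
            prev = w
        dims.append((prev, 1))
        self._dims = dims

        # full masks per affine (None = dense)
        self.masks: list[np.ndarray | None] = [None] * len(dims)
        m1 = np.ones(dims[0])
        m1[:p, :] = mask1_geno
        if self._inject[0]:
            m1[p:, :] = mask1_geno  # impact feature of SNP j follows its SNP's mask
        self.masks[0] = m1
        if mask2 is not None:
            m2 = np.ones(dims[1])
            m2[: widths[0], :] = mask2
            self.masks[1] = m2

        self.params: list[dict[str, np.ndarray]] = []

    # -- parameter handling ---------------------------------------------------

    def initialize(self, seed: int = 0) -> None:
        """Scaled-uniform weight initialization (masked entries zeroed)."""
        rng = np.random.default_rng(seed)
        self.params = []
        n_affine = len(self._dims)
        for l, (din, dout) in enumerate(self._dims):
            lim = np.sqrt(6.0 / (din + dout))
            w = rng.uniform(-lim, lim, size=(din, dout))
            n_inj = self._inject.get(l, 0)
            if n_inj:
                # annotation injections start as silent additive corrections:
                # their weights grow only under gradient pressure, so trained
                # magnitudes reflect learned relevance rather than init noise
                w[din - n_inj :, :] = 0.0
            if self.masks[l] is not None:
                w *= self.masks[l]
            layer = {"W": w, "b": np.zeros(dout)}
            if l < n_affine - 1 and self.spec.use_batch_norm:
                layer.update(
                    gamma=np.ones(dout), beta=np.zeros(dout),
                    rmean=np.zeros(dout), rvar=np.ones(dout),
                )
            self.params.append(layer)

    @property
    def weights(self) -> list[np.ndarray]:
        return [layer["W"] for layer in self.params]

    # -- features -------------------------------------------------------------

    def _injections(self, X: np.ndarray, fit_stats: bool) -> dict[int, np.ndarray]:
        """Per-sample annotation features injected in parallel at each layer.

        Layer 1: dosage-weighted allelic impact per SNP; layer 2: per-term
        gene-function activation (gene signals propagated through the
        gene x term score matrix); layer 3: per-metaterm module activation.
        Features are standardized with training-set statistics.
        """
        out: dict[int, np.ndarray] = {}
        impact = X * self._delta
        if self._inject[0]:
            out[0] = impact
        if self._inject[1] or self._inject[2]:
            gene_sig = impact @ self._snp_gene
            term = gene_sig @ self._gene_term
            if self._inject[1]:
                out[1] = term
            if self._inject[2]:
                out[2] = term @ self._term_meta
        for l, feats in out.items():
            if fit_stats or l not in self._inj_stats:
                mu = feats.mean(axis=0)
                # one scale per block: per-feature scaling would erase the
                # informative magnitude contrasts between annotation features
                # (large vs near-zero allelic deltas, dominant vs background
                # term and module activations)
                sd = np.array([feats.std() if feats.std() > 0 else 1.0])
                self._inj_stats[l] = (mu, sd)
            mu, sd = self._inj_stats[l]
            out[l] = (feats - mu) / sd
        return out

    # -- forward / backward ---------------------------------------------------

    def _forward(self, X, inj, training, dropout_rng=None, batch_stats=None):
        act, _ = _activation(self.spec.activation)
        if batch_stats is None:
            batch_stats = training
        a = X
        caches = []
        n_internal = len(self._dims) - 1
        for l in range(n_internal):
            inp = np.hstack([a, inj[l]]) if self._inject.get(l, 0) else a
            layer = self.params[l]
            z = inp @ layer["W"] + layer["b"]
            cache = {"inp": inp, "z": z}
            if self.spec.use_batch_norm:
                if batch_stats:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    if training:
                        m = self.spec.bn_momentum
                        layer["rmean"] = m * layer["rmean"] + (1 - m) * mu
                        layer["rvar"] = m * layer["rvar"] + (1 - m) * var
                else:
                    mu, var = layer["rmean"], layer["rvar"]
                xhat = (z - mu) / np.sqrt(var + _BN_EPS)
                zt = layer["gamma"] * xhat + layer["beta"]
                cache.update(xhat=xhat, var=var)
            else:
                zt = z
            h = act(zt)
            cache["zt"] = zt
            cache["hact"] = h
            if training and self.spec.dropout_rate > 0:
                keep = 1.0 - self.spec.dropout_rate
                dmask = (dropout_rng.random(h.shape) < keep) / keep
                h = h * dmask
                cache["dmask"] = dmask
            cache["h"] = h
            caches.append(cache)
            a = h
        out = self.params[-1]
        yhat = (a @ out["W"] + out["b"]).ravel()
        return yhat, a, caches

    def _backward(self, X, y, yhat, a_last, caches, grads):
        _, dact = _activation(self.spec.activation)
        n = len(y)
        dy = (2.0 / n) * (yhat - y)[:, None]
        out = self.params[-1]
        grads[-1]["W"] += a_last.T @ dy
        grads[-1]["b"] += dy.sum(axis=0)
        da = dy @ out["W"].T
        n_internal = len(self._dims) - 1
        for l in range(n_internal - 1, -1, -1):
            c = caches[l]
            dh = da
            if "dmask" in c:
                dh = dh * c["dmask"]
            dzt = dh * dact(c["zt"], c["hact"])
            layer = self.params[l]
            if self.spec.use_batch_norm:
                xhat = c["xhat"]
                grads[l]["gamma"] += (dzt * xhat).sum(axis=0)
                grads[l]["beta"] += dzt.sum(axis=0)
                std = np.sqrt(c["var"] + _BN_EPS)
                dxhat = dzt * layer["gamma"]
                dz = (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) / std
            else:
                dz = dzt
            grads[l]["W"] += c["inp"].T @ dz
            grads[l]["b"] += dz.sum(axis=0)
            dinp = dz @ layer["W"].T
            da = dinp[:, : self._dims[l][0] - self._inject.get(l, 0)] if self._inject.get(
                l, 0
            ) else dinp
        return da  # gradient w.r.t. genotype input (after layer 0 loop: da of X)

    # -- training -------------------------------------------------------------

    def train(
        self,
        genotypes: GenotypeMatrix,
        phenotypes: PhenotypeVector,
        steps: int,
        seed: int = 0,
        validation: tuple[GenotypeMatrix, PhenotypeVector] | None = None,
    ) -> "AnnotationNetwork":
        """Full-batch gradient descent with momentum; loss recorded per step.

        The recorded trace is the deterministic full-batch training loss
        evaluated after each update (dropout off, batch statistics), so the
        trace is reproducible and constant when the learning rate is zero.
        """
        if steps < 1:
            raise ValueError("steps must be >= 1")
        self._check_snps(genotypes)
        if not self.params:
            self.initialize(seed)
        X = genotypes.codes.astype(float)
        y = np.asarray(phenotypes.values, dtype=float)
        inj = self._injections(X, fit_stats=True)
        rng = np.random.default_rng(seed + 1)
        spec = self.spec
        k = 1 if spec.reg_norm == "L1" else 2
        coef = spec.penalty_coefficient * spec.reg_rate
        vel = [
            {key: np.zeros_like(val) for key, val in layer.items()
             if key in ("W", "b", "gamma", "beta")}
            for layer in self.params
        ]
        trace = np.empty(steps)
        val_trace = np.empty(steps) if validation is not None else None
        if validation is not None:
            Xv = validation[0].codes.astype(float)
            yv = np.asarray(validation[1].values, dtype=float)
            injv = self._injections(Xv, fit_stats=False)
        for step in range(steps):
            yhat, a_last, caches = self._forward(X, inj, training=True, dropout_rng=rng)
            if not np.isfinite(yhat).all():
                raise RuntimeError(f"non-finite predictions at training step {step + 1}")
            grads = [
                {key: np.zeros_like(val) for key, val in layer.items()
                 if key in ("W", "b", "gamma", "beta")}
                for layer in self.params
            ]
            self._backward(X, y, yhat, a_last, caches, grads)
            for l, layer in enumerate(self.params):
                gW = grads[l]["W"]
                gW += coef * (np.sign(layer["W"]) if k == 1 else 2.0 * layer["W"])
                if self.masks[l] is not None:
                    gW *= self.masks[l]
                for key in vel[l]:
                    vel[l][key] = spec.momentum * vel[l][key] - spec.learning_rate * grads[l][key]
                    layer[key] = layer[key] + vel[l][key]
                if self.masks[l] is not None:
                    layer["W"] *= self.masks[l]
            # deterministic trace: dropout off, batch statistics
            y_eval, _, _ = self._forward(X, inj, training=False, batch_stats=True)
            loss = compute_loss(y, y_eval, self.weights, spec.reg_norm, spec.reg_rate,
                                spec.penalty_coefficient)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at training step {step + 1}")
            trace[step] = loss
            if validation is not None:
                yv_hat, _, _ = self._forward(Xv, injv, training=False)
                val_trace[step] = float(np.mean((yv - yv_hat) ** 2))
        # training-set scale of every input feeding each affine: used by the
        # backward-tracing importance statistic (weight x input scale)
        _, _, caches_f = self._forward(X, inj, training=False, batch_stats=True)
        stds = {"genotype": X.std(axis=0)}
        for l, f in inj.items():
            stds[f"inj{l}"] = f.std(axis=0)
        for l, c in enumerate(caches_f):
            stds[f"h{l + 1}"] = c["h"].std(axis=0)
        self._act_stds = stds
        self.loss_trace = trace
        self.validation_trace = val_trace
        self._trained = True
        return self

    def input_scales(self, affine: int) -> np.ndarray:
        """Training-set std of each input row of the given affine map.

        Ones when the network has not been trained (pure weight magnitude).
        """
        din = self._dims[affine][0]
        stds = getattr(self, "_act_stds", None)
        if stds is None:
            return np.ones(din)
        p = len(self.snp_ids)
        if affine == 0:
            main = stds["genotype"]
        else:
            main = stds[f"h{affine}"]
        parts = [main]
        n_inj = self._inject.get(affine, 0)
        if n_inj:
            parts.append(stds[f"inj{affine}"])
        out = np.concatenate(parts)
        if len(out) != din:  # pragma: no cover - defensive
            return np.ones(din)
        return out

    @property
    def optimal_step(self) -> int:
        if self.loss_trace is None:
            raise RuntimeError("network has not been trained")
        return optimal_step(self.loss_trace)

    # -- inference ------------------------------------------------------------

    def _check_snps(self, genotypes: GenotypeMatrix) -> None:
        if genotypes.snps.snp_ids != self.snp_ids:
            raise ValueError("genotype SNP set does not match the network's SNP set")

    def predict(self, genotypes: GenotypeMatrix) -> PhenotypeVector:
        """Deterministic inference (dropout off, batch norm in running mode)."""
        self._check_snps(genotypes)
        if not self.params:
            raise RuntimeError("network not initialized")
        X = genotypes.codes.astype(float)
        inj = self._injections(X, fit_stats=False)
        yhat, _, _ = self._forward(X, inj, training=False)
        return PhenotypeVector("predicted", yhat)


    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint weights, spec, loss trace and feature statistics."""
        import json

        arrays: dict[str, np.ndarray] = {}
        for l, layer in enumerate(self.params):
            for key, val in layer.items():
                arrays[f"p{l}_{key}"] = val
        for l, (mu, sd) in self._inj_stats.items():
            arrays[f"inj{l}_mu"] = mu
            arrays[f"inj{l}_sd"] = sd
        if self.loss_trace is not None:
            arrays["loss_trace"] = self.loss_trace
        spec_json = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in vars(self.spec).items()}
        )
        np.savez(path, spec=np.array(spec_json), snp_ids=np.array(self.snp_ids), **arrays)

    def load(self, path) -> "AnnotationNetwork":
        """Restore a checkpoint into a freshly built network (same bundle)."""
        import json

        data = np.load(path, allow_pickle=False)
        spec_d = json.loads(str(data["spec"]))
        spec_d["unit_ratio"] = tuple(spec_d["unit_ratio"])
        if NetworkSpec(**spec_d).internal_widths != self.spec.internal_widths:
            raise ValueError("checkpoint architecture does not match this network")
        if list(data["snp_ids"]) != self.snp_ids:
            raise ValueError("checkpoint SNP set does not match this network")
        if not self.params:
            self.initialize(0)
        for l, layer in enumerate(self.params):
            for key in list(layer):
                layer[key] = data[f"p{l}_{key}"]
        self._inj_stats = {}
        for l in range(3):
            if f"inj{l}_mu" in data:
                self._inj_stats[l] = (data[f"inj{l}_mu"], data[f"inj{l}_sd"])
        if "loss_trace" in data:
            self.loss_trace = data["loss_trace"]
            self._trained = True
        return self


TrainedNetwork = AnnotationNetwork


def build_network(
    bundle: AnnotationBundle,
    impacts: ImpactScores,
    spec: NetworkSpec,
    genotypes: GenotypeMatrix,
    seed: int = 0,
) -> AnnotationNetwork:
    """Construct and initialize a network wired from the annotation bundle."""
    bundle.validate(genotypes.snps)
    net = AnnotationNetwork(
        spec,
        bundle,
        impacts,
        genotypes.snps.snp_ids,
        genotypes.snps.frame["category"].tolist(),
    )
    net.initialize(seed)
    return net


def train_network(
    net: AnnotationNetwork,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    steps: int,
    seed: int = 0,
    validation=None,
) -> AnnotationNetwork:
    return net.train(genotypes, phenotypes, steps, seed=seed, validation=validation)


def predict(net: AnnotationNetwork, genotypes: GenotypeMatrix) -> PhenotypeVector:
    return net.predict(genotypes)
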