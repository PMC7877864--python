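"""Model facade: a fit/results interface over the QSP machinery.

:class:`CrohnsQSPModel` bundles a nominal parameter set, the drug
mechanisms, and the PK library, and exposes the full workflow — population
generation and trial matching, arm and combination simulation, responder
classification — as methods. :meth:`CrohnsQSPModel.fit` calibrates selected
parameters against clinical targets and returns a
:class:`~ibdqsp.calibrate.CalibrationResult` whose ``.model`` attribute is a
new, fitted model instance, in the spirit of statsmodels' model/results
split.
"""

from __future__ import annotations

from dataclasses import replace

from .binding import builtin_mechanisms
from .calibrate import (CalibrationProblem, CalibrationResult, calibrate)
from .dynamics import DEFAULT_SOLVER, SolverSettings, simulate, steady_state
from .network import NetworkDefinition, build_network
from .params import ParameterSet, nominal_parameters
from .pk import PKParameters, Regimen, default_pk_parameters
from .population import (BaselineTargets, Cohort, PlausibilityWindow,
                         generate_cohort, select_trial_population)
from .trial import (ArmResult, ResponderPartition, ResponseCriterion,
                    TrialSpec, classify_responders, simulate_arm,
                    simulate_combination)

__all__ = ["CrohnsQSPModel"]


class CrohnsQSPModel:
    """The Crohn's disease immune-network model with drugs attached.

    Parameters
    ----------
    params
        Nominal mechanistic parameters (default: the designed nominal set).
    mechanisms
        Drug -> :class:`~ibdqsp.binding.DrugMechanism`; default: the five
        built-in antibodies.
    pk_library
        Drug -> :class:`~ibdqsp.pk.PKParameters`; default: repo defaults.
    solver
        Stiff ODE solver settings shared by all simulations.
    """

    def __init__(self, params: ParameterSet | None = None,
                 mechanisms=None,
                 pk_library: dict[str, PKParameters] | None = None,
                 solver: SolverSettings = DEFAULT_SOLVER):
        self.params = params if params is not None else nominal_parameters()
        self.mechanisms = (mechanisms if mechanisms is not None
                           else builtin_mechanisms())
        self.pk_library = (pk_library if pk_library is not None
                           else default_pk_parameters())
        self.solver = solver
        self._network: NetworkDefinition | None = None

    # ------------------------------------------------------------- basics
    @property
    def network(self) -> NetworkDefinition:
        if self._network is None:
            self._network = build_network()
            self._network.validate(self.params)
        return self._network

    def with_params(self, params: ParameterSet,
                    kd_overrides: dict[str, float] | None = None,
                    ) -> "CrohnsQSPModel":
        """New model instance with replaced parameters / drug affinities."""
        mechanisms = dict(self.mechanisms)
        for drug, kd in (kd_overrides or {}).items():
            mechanisms[drug] = replace(mechanisms[drug], Kd=kd)
        return CrohnsQSPModel(params=params, mechanisms=mechanisms,
                              pk_library=self.pk_library, solver=self.solver)

    def steady_state(self, params: ParameterSet | None = None):
        return steady_state(params or self.params, solver=self.solver)

    def simulate_patient(self, patient, horizon_days: float,
                         free_fraction_timecourse=None, grid=None,
                         breakpoints=()):
        return simulate(patient, horizon_days, free_fraction_timecourse,
                        grid=grid, breakpoints=breakpoints, solver=self.solver)

    # --------------------------------------------------------- population
    def generate_population(self, n: int, seed: int = 0, priors=None,
                            window: PlausibilityWindow | None = None,
                            ) -> Cohort:
        return generate_cohort(n=n, priors=priors, seed=seed,
                               params=self.params, window=window,
                               solver=self.solver)

    def select_population(self, cohort: Cohort, targets: BaselineTargets,
                          n_out: int, seed: int = 0) -> Cohort:
        return select_trial_population(cohort, targets, n_out, seed=seed)

    # -------------------------------------------------------------- trials
    def simulate_arm(self, population: Cohort, regimens,
                     spec: TrialSpec | None = None, name: str = "",
                     ) -> ArmResult:
        return simulate_arm(population, regimens, spec=spec,
                            mechanisms=self.mechanisms,
                            pk_library=self.pk_library,
                            solver=self.solver, name=name)

    def simulate_combination(self, population: Cohort, regimen_A: Regimen,
                             regimen_B: Regimen,
                             spec: TrialSpec | None = None):
        return simulate_combination(population, regimen_A, regimen_B,
                                    spec=spec, mechanisms=self.mechanisms,
                                    pk_library=self.pk_library,
                                    solver=self.solver)

    @staticmethod
    def classify_responders(results_A: ArmResult, results_B: ArmResult,
                            criterion: ResponseCriterion) -> ResponderPartition:
        return classify_responders(results_A, results_B, criterion)

    # ---------------------------------------------------------------- fit
    def fit(self, targets, population: Cohort, param_names,
            seed: int = 0, maxfev: int = 60, n_starts: int = 1,
            bound_log10: float = 2.0) -> CalibrationResult:
        """Calibrate the named parameters against clinical targets.

        ``targets`` are :class:`~ibdqsp.calibrate.CalibrationTarget`;
        ``population`` is the frozen surrogate cohort the objective is
        evaluated over; ``param_names`` may mix ParameterSet fields and
        ``"Kd:<drug>"`` entries. Returns a results object whose ``.model``
        is a new fitted :class:`CrohnsQSPModel`.
        """
        problem = CalibrationProblem(targets, self.params, population,
                                     mechanisms=self.mechanisms,
                                     pk_library=self.pk_library,
                                     solver=self.solver)
        kd_start = {name[3:]: self.mechanisms[name[3:]].Kd
                    for name in param_names if name.startswith("Kd:")}
        result = calibrate(problem, param_names, seed=seed, maxfev=maxfev,
                           n_starts=n_starts, bound_log10=bound_log10,
                           kd_start=kd_start)
        result.model = self.with_params(result.params, result.kd_overrides)
        return result

    def __repr__(self) -> str:  # pragma: no cover
        drugs = ", ".join(self.mechanisms)
        return f"CrohnsQSPModel(drugs=[{drugs}], solver={self.solver.method})"
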