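{
  "$defs": {
    "AnalysisSettings": {
      "additionalProperties": false,
      "description": "Analysis-wide options.\n\n``effectiveness_mode='utility_at_horizon'`` reports the terminal utility\nitself as the QALY outcome; ``'time_integrated'`` integrates the utility\nover the horizon with continuous discounting at ``discount_rate``.",
      "properties": {
        "wtp": {
          "default": 12876.0,
          "title": "Wtp",
          "type": "number"
        },
        "discount_rate": {
          "default": 0.03,
          "title": "Discount Rate",
          "type": "number"
        },
        "horizon_months": {
          "default": 18.0,
          "title": "Horizon Months",
          "type": "number"
        },
        "effectiveness_mode": {
          "default": "utility_at_horizon",
          "enum": [
            "utility_at_horizon",
            "time_integrated"
          ],
          "title": "Effectiveness Mode",
          "type": "string"
        },
        "psa_draws": {
          "default": 5000,
          "title": "Psa Draws",
          "type": "integer"
        },
        "seed": {
          "default": 2022,
          "title": "Seed",
          "type": "integer"
        }
      },
      "title": "AnalysisSettings",
      "type": "object"
    },
    "Branch": {
      "additionalProperties": false,
      "properties": {
        "prob": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "number"
            },
            {
              "type": "integer"
            }
          ],
          "title": "Prob"
        },
        "node": {
          "$ref": "#/$defs/TreeNode"
        }
      },
      "required": [
        "prob",
        "node"
      ],
      "title": "Branch",
      "type": "object"
    },
    "DecisionTree": {
      "additionalProperties": false,
      "description": "A single decision root whose children are the strategy subtrees.",
      "properties": {
        "label": {
          "default": "decision",
          "title": "Label",
          "type": "string"
        },
        "strategies": {
          "items": {
            "$ref": "#/$defs/TreeNode"
          },
          "title": "Strategies",
          "type": "array"
        }
      },
      "required": [
        "strategies"
      ],
      "title": "DecisionTree",
      "type": "object"
    },
    "DistributionSpec": {
      "additionalProperties": false,
      "description": "Sampling distribution of a parameter for probabilistic sensitivity analysis.\n\n``beta`` and ``gamma`` are parameterised by (mean, se) and fitted by the\nmethod of moments; ``uniform`` spans mean \u00b1 sqrt(3)\u00b7se; ``fixed`` is\ndegenerate at the parameter's base value.",
      "properties": {
        "family": {
          "enum": [
            "beta",
            "gamma",
            "uniform",
            "fixed"
          ],
          "title": "Family",
          "type": "string"
        },
        "mean": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Mean"
        },
        "se": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Se"
        }
      },
      "required": [
        "family"
      ],
      "title": "DistributionSpec",
      "type": "object"
    },
    "Parameter": {
      "additionalProperties": false,
      "description": "A named model input with base value, plausible range, and PSA distribution.\n\n``low``/``high`` are the deterministic-sensitivity range (defaulting to a\nzero-width range at ``base``); ``dist`` drives probabilistic sampling.",
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "kind": {
          "enum": [
            "probability",
            "utility",
            "cost",
            "rate",
            "count"
          ],
          "title": "Kind",
          "type": "string"
        },
        "base": {
          "title": "Base",
          "type": "number"
        },
        "low": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Low"
        },
        "high": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "High"
        },
        "dist": {
          "anyOf": [
            {
              "$ref": "#/$defs/DistributionSpec"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        },
        "note": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Note"
        }
      },
      "required": [
        "name",
        "kind",
        "base"
      ],
      "title": "Parameter",
      "type": "object"
    },
    "TreeNode": {
      "additionalProperties": false,
      "description": "A chance or terminal node.\n\nChance nodes carry ordered branches, each with a probability expression\n(or the ``complement`` keyword on at most one branch).  Terminal nodes\ncarry ``cost`` and ``effect`` payoff expressions.",
      "properties": {
        "label": {
          "title": "Label",
          "type": "string"
        },
        "kind": {
          "enum": [
            "chance",
            "terminal"
          ],
          "title": "Kind",
          "type": "string"
        },
        "branches": {
          "items": {
            "$ref": "#/$defs/Branch"
          },
          "title": "Branches",
          "type": "array"
        },
        "cost": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "number"
            },
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Cost"
        },
        "effect": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "number"
            },
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Effect"
        }
      },
      "required": [
        "label",
        "kind"
      ],
      "title": "TreeNode",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Top-level schema of a model configuration file.",
  "properties": {
    "schema_version": {
      "default": 1,
      "title": "Schema Version",
      "type": "integer"
    },
    "parameters": {
      "items": {
        "$ref": "#/$defs/Parameter"
      },
      "title": "Parameters",
      "type": "array"
    },
    "tree": {
      "$ref": "#/$defs/DecisionTree"
    },
    "settings": {
      "$ref": "#/$defs/AnalysisSettings"
    }
  },
  "required": [
    "parameters",
    "tree"
  ],
  "title": "ModelConfig",
  "type": "object",
  "$id": "ceatree-model-config-v1"
}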