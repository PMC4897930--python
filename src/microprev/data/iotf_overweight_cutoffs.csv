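# International Obesity Taskforce age- and sex-specific BMI thresholds (kg/m^2)
# equivalent to adult BMI 25 at age 18, by half-year of age.
# Source: Cole TJ, Bellizzi MC, Flegal KM, Dietz WH. Establishing a standard
# definition for child overweight and obesity worldwide: international survey.
# BMJ 2000;320:1240. (Ages 12-18 subset.)
age_years,male,female
12.0,21.22,21.68
12.5,21.56,22.14
13.0,21.91,22.58
13.5,22.27,22.98
14.0,22.62,23.34
14.5,22.96,23.66
15.0,23.29,23.94
15.5,23.60,24.17
16.0,23.90,24.37
16.5,24.19,24.54
17.0,24.46,24.70
17.5,24.73,24.85
18.0,25.00,25.00
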