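w1,T_K,x3_e4,sd_e4
0.00,278.15,3.84,0.033
0.00,283.15,4.89,0.05
0.00,288.15,6.02,0.01
0.00,293.15,7.47,0.04
0.00,298.15,9.18,0.07
0.00,303.15,10.87,0.14
0.00,308.15,12.99,0.23
0.00,313.15,16.23,0.16
0.00,318.15,18.96,0.15
0.05,278.15,4.14,0.05
0.05,283.15,5.3,0.05
0.05,288.15,6.52,0.09
0.05,293.15,8.12,0.04
0.05,298.15,9.94,0.07
0.05,303.15,11.78,0.09
0.05,308.15,13.95,0.24
0.05,313.15,17.32,0.09
0.05,318.15,20.51,0.19
0.10,278.15,4.47,0.05
0.10,283.15,5.7,0.08
0.10,288.15,6.97,0.07
0.10,293.15,8.53,0.03
0.10,298.15,10.58,0.13
0.10,303.15,12.74,0.19
0.10,308.15,15.09,0.13
0.10,313.15,18.77,0.15
0.10,318.15,21.73,0.07
0.15,278.15,4.85,0.06
0.15,283.15,6.12,0.09
0.15,288.15,7.6,0.09
0.15,293.15,9.3,0.14
0.15,298.15,11.47,0.22
0.15,303.15,13.77,0.19
0.15,308.15,16.1,0.14
0.15,313.15,20.36,0.14
0.15,318.15,23.59,0.15
0.20,278.15,5.28,0.04
0.20,283.15,6.59,0.06
0.20,288.15,8.26,0.07
0.20,293.15,10.04,0.13
0.20,298.15,12.37,0.19
0.20,303.15,14.67,0.04
0.20,308.15,17.61,0.08
0.20,313.15,21.98,0.14
0.20,318.15,25.62,0.34
0.25,278.15,5.62,0.09
0.25,283.15,7.14,0.04
0.25,288.15,8.83,0.1
0.25,293.15,10.75,0.14
0.25,298.15,13.4,0.19
0.25,303.15,15.99,0.19
0.25,308.15,18.63,0.20
0.25,313.15,23.26,0.21
0.25,318.15,27.76,0.13
0.30,278.15,6.08,0.10
0.30,283.15,7.68,0.05
0.30,288.15,9.41,0.14
0.30,293.15,11.42,0.05
0.30,298.15,14.56,0.07
0.30,303.15,17.36,0.12
0.30,308.15,20.29,0.4
0.30,313.15,25.17,0.25
0.30,318.15,29.32,0.33
0.35,278.15,6.52,0.08
0.35,283.15,8.2,0.03
0.35,288.15,10.15,0.23
0.35,293.15,12.42,0.16
0.35,298.15,15.72,0.17
0.35,303.15,18.70,0.15
0.35,308.15,21.7,0.17
0.35,313.15,26.7,0.07
0.35,318.15,31.82,0.4
0.40,278.15,7.27,0.14
0.40,283.15,9.15,0.10
0.40,288.15,11.44,0.03
0.40,293.15,13.96,0.05
0.40,298.15,17.16,0.24
0.40,303.15,20.66,0.25
0.40,308.15,24.49,0.15
0.40,313.15,30.01,0.2
0.40,318.15,35.08,0.5
0.45,278.15,7.57,0.02
0.45,283.15,9.66,0.18
0.45,288.15,11.99,0.11
0.45,293.15,14.61,0.15
0.45,298.15,18.13,0.22
0.45,303.15,21.95,0.15
0.45,308.15,25.49,0.4
0.45,313.15,31.18,0.4
0.45,318.15,36.61,0.24
0.50,278.15,8.27,0.11
0.50,283.15,10.46,0.08
0.50,288.15,12.73,0.08
0.50,293.15,15.69,0.29
0.50,298.15,19.44,0.36
0.50,303.15,23.40,0.29
0.50,308.15,27.51,0.13
0.50,313.15,33.69,0.4
0.50,318.15,39.82,0.32
0.55,278.15,8.96,0.08
0.55,283.15,11.14,0.10
0.55,288.15,13.93,0.16
0.55,293.15,16.99,0.17
0.55,298.15,21.11,0.36
0.55,303.15,25.4,0.5
0.55,308.15,29.61,0.17
0.55,313.15,35.69,0.24
0.55,318.15,43.12,0.23
0.60,278.15,9.65,0.12
0.60,283.15,12.06,0.04
0.60,288.15,14.96,0.12
0.60,293.15,18.07,0.14
0.60,298.15,22.96,0.21
0.60,303.15,27.25,0.24
0.60,308.15,31.65,0.24
0.60,313.15,39.1,0.49
0.60,318.15,45.76,0.8
0.65,278.15,10.62,0.23
0.65,283.15,12.92,0.12
0.65,288.15,16.08,0.29
0.65,293.15,19.36,0.21
0.65,298.15,24.6,0.5
0.65,303.15,29.46,0.16
0.65,308.15,34.34,0.21
0.65,313.15,42.27,0.36
0.65,318.15,49.29,0.7
0.70,278.15,11.33,0.23
0.70,283.15,14.04,0.13
0.70,288.15,17.34,0.27
0.70,293.15,20.94,0.13
0.70,298.15,26.28,0.3
0.70,303.15,31.71,0.54
0.70,308.15,36.81,0.4
0.70,313.15,45.24,0.23
0.70,318.15,52.83,0.6
0.75,278.15,12.38,0.22
0.75,283.15,15.40,0.06
0.75,288.15,18.6,0.14
0.75,293.15,22.48,0.28
0.75,298.15,28.73,0.26
0.75,303.15,33.84,0.24
0.75,308.15,40.43,0.28
0.75,313.15,48.66,0.13
0.75,318.15,57.7,0.6
0.80,278.15,13.29,0.26
0.80,283.15,16.51,0.17
0.80,288.15,20.01,0.25
0.80,293.15,24.58,0.15
0.80,298.15,30.81,0.08
0.80,303.15,36.9,0.4
0.80,308.15,43.03,0.5
0.80,313.15,52.14,0.7
0.80,318.15,61.1,0.7
0.85,278.15,14.48,0.21
0.85,283.15,17.57,0.30
0.85,288.15,21.95,0.23
0.85,293.15,26.13,0.4
0.85,298.15,33.35,0.4
0.85,303.15,39.6,0.5
0.85,308.15,46.09,0.2
0.85,313.15,55.04,0.05
0.85,318.15,66.53,0.8
0.90,278.15,15.6,0.1
0.90,283.15,19.03,0.29
0.90,288.15,23.6,0.3
0.90,293.15,28.18,0.4
0.90,298.15,35.68,0.4
0.90,303.15,43.0,0.5
0.90,308.15,49.87,0.5
0.90,313.15,59.91,0.6
0.90,318.15,71.36,1
0.95,278.15,16.51,0.09
0.95,283.15,20.44,0.20
0.95,288.15,25.11,0.19
0.95,293.15,29.97,0.06
0.95,298.15,38.49,0.31
0.95,303.15,45.77,0.13
0.95,308.15,53.49,0.4
0.95,313.15,64.27,1.1
0.95,318.15,76.53,0.9
1.00,278.15,17.8,0.35
1.00,283.15,22.04,0.11
1.00,288.15,27.14,0.13
1.00,293.15,33.1,0.32
1.00,298.15,41.52,0.3
1.00,303.15,50.8,0.9
1.00,308.15,58.12,0.4
1.00,313.15,69.95,1.7
1.00,318.15,83.07,0.6
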