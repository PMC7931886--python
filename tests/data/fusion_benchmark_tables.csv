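dataset,model,n,f1,precision,recall,auc
padchest,Image Only (Square),1,0.28,0.40,0.22,0.72
padchest,Image Only (Square),2,0.24,0.40,0.18,0.71
padchest,Image Only (Square),4,0.21,0.34,0.15,0.69
padchest,Text Only (Wide),1,0.70,0.80,0.62,0.96
padchest,Text Only (Wide),2,0.52,0.69,0.42,0.92
padchest,Text Only (Wide),4,0.34,0.51,0.26,0.86
padchest,Early Fusion (Square),1,0.84,0.89,0.79,0.98
padchest,Early Fusion (Square),2,0.75,0.83,0.67,0.96
padchest,Early Fusion (Square),4,0.62,0.75,0.53,0.93
padchest,Early Fusion (Wide),1,0.63,0.77,0.53,0.95
padchest,Early Fusion (Wide),2,0.43,0.67,0.32,0.90
padchest,Early Fusion (Wide),4,0.25,0.40,0.19,0.83
padchest,"Late Fusion (Wide, Square)",1,0.64,0.86,0.51,0.95
padchest,"Late Fusion (Wide, Square)",2,0.46,0.72,0.34,0.90
padchest,"Late Fusion (Wide, Square)",4,0.32,0.44,0.25,0.80
padchest,"Late Fusion (Wide, Square, Pretrained)",1,0.71,0.91,0.58,0.96
padchest,"Late Fusion (Wide, Square, Pretrained)",2,0.55,0.78,0.42,0.92
padchest,"Late Fusion (Wide, Square, Pretrained)",4,0.37,0.53,0.28,0.84
padchest,"Model Fusion (Wide, Square)",1,0.70,0.80,0.63,0.95
padchest,"Model Fusion (Wide, Square)",2,0.56,0.71,0.46,0.92
padchest,"Model Fusion (Wide, Square)",4,0.38,0.56,0.28,0.85
padchest,"Model Fusion (Wide, Square, Pretrained)",1,0.79,0.85,0.74,0.96
padchest,"Model Fusion (Wide, Square, Pretrained)",2,0.64,0.75,0.55,0.93
padchest,"Model Fusion (Wide, Square, Pretrained)",4,0.43,0.61,0.34,0.87
indiana,Image Only (Square),1,0.46,0.52,0.42,0.61
indiana,Image Only (Square),2,0.38,0.53,0.30,0.57
indiana,Image Only (Square),4,0.38,0.49,0.30,0.56
indiana,Text Only (Wide),1,0.88,0.80,0.97,0.92
indiana,Text Only (Wide),2,0.86,0.77,0.97,0.90
indiana,Text Only (Wide),4,0.79,0.72,0.87,0.84
indiana,Early Fusion (Square),1,0.89,0.87,0.90,0.92
indiana,Early Fusion (Square),2,0.86,0.85,0.87,0.89
indiana,Early Fusion (Square),4,0.82,0.80,0.85,0.86
indiana,Early Fusion (Wide),1,0.91,0.90,0.92,0.93
indiana,Early Fusion (Wide),2,0.86,0.79,0.94,0.90
indiana,Early Fusion (Wide),4,0.79,0.69,0.91,0.84
indiana,"Late Fusion (Wide, Square)",1,0.89,0.82,0.96,0.93
indiana,"Late Fusion (Wide, Square)",2,0.84,0.75,0.95,0.88
indiana,"Late Fusion (Wide, Square)",4,0.79,0.70,0.89,0.84
indiana,"Late Fusion (Wide, Square, Pretrained)",1,0.89,0.83,0.96,0.93
indiana,"Late Fusion (Wide, Square, Pretrained)",2,0.86,0.78,0.96,0.90
indiana,"Late Fusion (Wide, Square, Pretrained)",4,0.82,0.74,0.91,0.86
indiana,"Model Fusion (Wide, Square)",1,0.86,0.76,0.97,0.91
indiana,"Model Fusion (Wide, Square)",2,0.84,0.74,0.97,0.89
indiana,"Model Fusion (Wide, Square)",4,0.80,0.69,0.95,0.85
indiana,"Model Fusion (Wide, Square, Pretrained)",1,0.86,0.78,0.97,0.91
indiana,"Model Fusion (Wide, Square, Pretrained)",2,0.85,0.76,0.97,0.89
indiana,"Model Fusion (Wide, Square, Pretrained)",4,0.81,0.71,0.94,0.86
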