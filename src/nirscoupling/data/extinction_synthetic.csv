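wavelength_nm,eps_hbo2,eps_hhb,eps_oxcco,dpf
780.0,7.00000000e-04,1.19018414e-03,5.81920918e-04,4.00
782.0,7.09188889e-04,1.17551433e-03,6.41061042e-04,4.00
784.0,7.18422222e-04,1.16058174e-03,7.03427059e-04,4.00
786.0,7.27700000e-04,1.14547313e-03,7.68817082e-04,4.00
788.0,7.37022222e-04,1.13027275e-03,8.36972612e-04,4.00
790.0,7.46388889e-04,1.11506091e-03,9.07577537e-04,4.00
792.0,7.55800000e-04,1.09991264e-03,9.80258233e-04,4.00
794.0,7.65255556e-04,1.08489664e-03,1.05458485e-03,4.00
796.0,7.74755556e-04,1.07007445e-03,1.13007385e-03,4.00
798.0,7.84300000e-04,1.05549981e-03,1.20619185e-03,4.00
800.0,7.93888889e-04,1.04121830e-03,1.28236078e-03,4.00
802.0,8.03522222e-04,1.02726719e-03,1.35796423e-03,4.00
804.0,8.13200000e-04,1.01367551e-03,1.43235511e-03,4.00
806.0,8.22922222e-04,1.00046429e-03,1.50486431e-03,4.00
808.0,8.32688889e-04,9.87646997e-04,1.57481032e-03,4.00
810.0,8.42500000e-04,9.75230050e-04,1.64150962e-03,4.00
812.0,8.52355556e-04,9.63213514e-04,1.70428758e-03,4.00
814.0,8.62255556e-04,9.51591815e-04,1.76248973e-03,4.00
816.0,8.72200000e-04,9.40354516e-04,1.81549300e-03,4.00
818.0,8.82188889e-04,9.29487121e-04,1.86271680e-03,4.00
820.0,8.92222222e-04,9.18971860e-04,1.90363357e-03,4.00
822.0,9.02300000e-04,9.08788459e-04,1.93777856e-03,4.00
824.0,9.12422222e-04,8.98914853e-04,1.96475863e-03,4.00
826.0,9.22588889e-04,8.89327849e-04,1.98425980e-03,4.00
828.0,9.32800000e-04,8.80003718e-04,1.99605328e-03,4.00
830.0,9.43055556e-04,8.70918712e-04,2.00000000e-03,4.00
832.0,9.53355556e-04,8.62049501e-04,1.99605328e-03,4.00
834.0,9.63700000e-04,8.53373536e-04,1.98425980e-03,4.00
836.0,9.74088889e-04,8.44869332e-04,1.96475863e-03,4.00
838.0,9.84522222e-04,8.36516685e-04,1.93777856e-03,4.00
840.0,9.95000000e-04,8.28296815e-04,1.90363357e-03,4.00
842.0,1.00552222e-03,8.20192464e-04,1.86271680e-03,4.00
844.0,1.01608889e-03,8.12187932e-04,1.81549300e-03,4.00
846.0,1.02670000e-03,8.04269075e-04,1.76248973e-03,4.00
848.0,1.03735556e-03,7.96423270e-04,1.70428758e-03,4.00
850.0,1.04805556e-03,7.88639349e-04,1.64150962e-03,4.00
852.0,1.05880000e-03,7.80907517e-04,1.57481032e-03,4.00
854.0,1.06958889e-03,7.73219252e-04,1.50486431e-03,4.00
856.0,1.08042222e-03,7.65567200e-04,1.43235511e-03,4.00
858.0,1.09130000e-03,7.57945061e-04,1.35796423e-03,4.00
860.0,1.10222222e-03,7.50347482e-04,1.28236078e-03,4.00
862.0,1.11318889e-03,7.42769943e-04,1.20619185e-03,4.00
864.0,1.12420000e-03,7.35208661e-04,1.13007385e-03,4.00
866.0,1.13525556e-03,7.27660487e-04,1.05458485e-03,4.00
868.0,1.14635556e-03,7.20122819e-04,9.80258233e-04,4.00
870.0,1.15750000e-03,7.12593523e-04,9.07577537e-04,4.00
872.0,1.16868889e-03,7.05070860e-04,8.36972612e-04,4.00
874.0,1.17992222e-03,6.97553421e-04,7.68817082e-04,4.00
876.0,1.19120000e-03,6.90040073e-04,7.03427059e-04,4.00
878.0,1.20252222e-03,6.82529911e-04,6.41061042e-04,4.00
880.0,1.21388889e-03,6.75022214e-04,5.81920918e-04,4.00
882.0,1.22530000e-03,6.67516415e-04,5.26153933e-04,4.00
884.0,1.23675556e-03,6.60012070e-04,4.73855517e-04,4.00
886.0,1.24825556e-03,6.52508831e-04,4.25072815e-04,4.00
888.0,1.25980000e-03,6.45006428e-04,3.79808771e-04,4.00
890.0,1.27138889e-03,6.37504656e-04,3.38026631e-04,4.00
892.0,1.28302222e-03,6.30003356e-04,2.99654713e-04,4.00
894.0,1.29470000e-03,6.22502407e-04,2.64591310e-04,4.00
896.0,1.30642222e-03,6.15001717e-04,2.32709606e-04,4.00
898.0,1.31818889e-03,6.07501219e-04,2.03862484e-04,4.00
900.0,1.33000000e-03,6.00000861e-04,1.77887152e-04,4.00
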