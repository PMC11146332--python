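# Independent FAO-56 Penman-Monteith reference implementation (Allen et al.
# 1998), coded from the handbook equations in R, with no code shared with the
# Python package. Used to freeze the oracle fixture in tests/data/:
#
#   Rscript fao56_reference.R inputs.csv outputs.csv
#
# inputs.csv columns: tmin,tmax,ws,rh,sr,doy,lat,elev
# outputs.csv adds:   es,ea,gamma,ra,rso,rn,et0

args <- commandArgs(trailingOnly = TRUE)
x <- read.csv(args[1])

e0 <- function(t) 0.6108 * exp(17.27 * t / (t + 237.3))

es <- (e0(x$tmax) + e0(x$tmin)) / 2
ea <- x$rh / 100 * es
tmean <- (x$tmin + x$tmax) / 2
delta <- 4098 * e0(tmean) / (tmean + 237.3)^2
pres <- 101.3 * ((293 - 0.0065 * x$elev) / 293)^5.26
gamma <- 0.000665 * pres

phi <- x$lat * pi / 180
dr <- 1 + 0.033 * cos(2 * pi / 365 * x$doy)
sdec <- 0.409 * sin(2 * pi / 365 * x$doy - 1.39)
omega <- acos(pmin(pmax(-tan(phi) * tan(sdec), -1), 1))
gsc <- 0.0820
ra <- 24 * 60 / pi * gsc * dr *
  (omega * sin(phi) * sin(sdec) + cos(phi) * cos(sdec) * sin(omega))
rso <- (0.75 + 2e-5 * x$elev) * ra
rns <- (1 - 0.23) * x$sr
ratio <- pmin(pmax(x$sr / rso, 0.05), 1)
sigma <- 4.903e-9
rnl <- sigma * ((x$tmax + 273.16)^4 + (x$tmin + 273.16)^4) / 2 *
  (0.34 - 0.14 * sqrt(ea)) * (1.35 * ratio - 0.35)
rn <- rns - rnl

et0 <- (0.408 * delta * rn +
        gamma * 900 / (tmean + 273) * x$ws * (es - ea)) /
       (delta + gamma * (1 + 0.34 * x$ws))

out <- cbind(x, es = es, ea = ea, gamma = gamma, ra = ra, rso = rso,
             rn = rn, et0 = et0)
write.csv(format(out, digits = 12, trim = TRUE), args[2],
          row.names = FALSE, quote = FALSE)
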